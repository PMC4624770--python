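# Published probabilistic mean results of the original evaluation (per person,
# 5 years after end of treatment; NMB at a 20000 GBP/QALY threshold). Used to
# validate the incremental-analysis routines against the published dominance
# structure; not consumed by the model itself.
id,pct_well_5y,mean_qaly,mean_cost,mean_nmb,published_rank
icbt_cw,50.25,3.75,6178,68810,1
icbt_general,41.40,3.64,5714,67040,2
icbt_hope,37.52,3.59,5853,65916,6
icbt_short,36.25,3.57,5970,65479,9
phenelzine,34.80,3.57,4557,66899,3
shws_internet,34.02,3.54,5186,65699,7
shws_book,33.59,3.54,4741,66037,5
gcbt_general,33.54,3.54,5436,65327,11
shns_book,33.28,3.53,4501,66197,4
exposure,33.00,3.53,5448,65179,14
gcbt_heimberg,32.40,3.52,5463,65013,17
paroxetine,30.01,3.51,4561,65603,8
venlafaxine,29.46,3.50,4633,65380,10
fluvoxamine,29.08,3.50,4666,65245,12
sertraline,28.75,3.49,4583,65239,13
shns_internet,29.55,3.49,5042,64714,20
escitalopram,28.12,3.48,4591,65058,15
fluoxetine,27.98,3.48,4597,65016,16
pdpt,28.80,3.48,6509,63055,25
citalopram,27.53,3.47,4602,64890,18
mirtazapine,27.18,3.47,4611,64786,19
moclobemide,25.95,3.45,4740,64323,21
pregabalin,25.78,3.45,4898,64118,22
ipt,25.44,3.44,5987,62728,27
mindfulness,24.86,3.43,5041,63527,23
pill_placebo,22.29,3.40,4713,63360,24
supportive,22.89,3.40,5934,62136,28
wait_list,20.43,3.37,4593,62810,26
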