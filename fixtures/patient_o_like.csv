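week,load_cm3,err_cm3
0,10,3.3669917341364193
3,15.086167868351227,4.3176841578133986
6,9.9130334851599677,3.160353767269227
9,4.9486013271706328,2.036624865852827
18,1.3084808927293561,0.86068911756574462
27,0.56055528941517385,0.49117442466545902
36,0.30265994802786911,0.46086370441945584
45,0.61641352886463896,0.5486838546967745
54,0.90901688136483194,0.58267421858342439
63,1.0085926886503307,0.55368183479864586
72,0.52127621282641712,0.53465464645721972
81,0.6545237360477727,0.54007023789768238
90,0.98482046185606109,0.54833800279910561
99,0.56684178990250045,0.54826471038643676
108,0.58611489479654921,0.54519065253036492
117,0.71751587250613724,0.54448406197623855
126,0.6887019741440179,0.54544119643079836
135,0.50901228398481402,0.54592922671462363
144,0.46403280706490868,0.54569304472524394
153,0.48435723725493612,0.54545744036488397
162,0.39637391315321052,0.54548805495179464
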