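ko	pfam
K00577	PF09472
K00205	PF01913
K23229	PF01913
K23229	PF04961
K12234	PF01996
K23230	PF08443
K00441	PF04422
K10946	PF04896
K00925	PF00871
K00625	PF01515
K00198	PF03063
K00600	PF00464
K01007	PF01326
K00016	PF00056
K00121	PF08240
K01595	PF00311
K00024	PF00056
K03594	PF00210
K02703	PF00124
K00036	PF00479
K01689	PF00113
K00873	PF00224
K01810	PF00342
K00134	PF00044
K00850	PF00365
K01623	PF00274
K00927	PF00162
K01834	PF00300
K00239	PF00890
K01902	PF08442
K00031	PF00180
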