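# Default loop model: coefficients averaged over ten models trained on
# this package's own synthetic calibration genomes (seeds 1000-1009,
# default SimConfig). SYNTHETIC calibration: these are NOT coefficients
# trained on experimental GM12878 ChIP-seq / Hi-C data, which require
# external downloads to regenerate. Retrain on real data for real use.
format=chiploop-model-v1
provenance=averaged
cutoff=0.22901913695420775
features=intercept,d,o_forward,o_reverse,o_divergent,s,r_track
coef.intercept=-1.9043551227424564
coef.d=-2.966965927921146e-05
coef.o_forward=-1.6010810790780377
coef.o_reverse=-1.576627322909363
coef.o_divergent=-1.5128467370321914
coef.s=-0.01225086326813489
coef.r_track=4.789002856186812
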