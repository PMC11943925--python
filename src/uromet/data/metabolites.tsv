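# Synthetic urine metabolite library (editable configuration).
# Chemical-shift positions and relative intensities are rounded values from
# public NMR reference compilations; baseline log-normal parameters are this
# package's defaults for a realistic mouse-urine dynamic range.
# Columns: name	affected	log_mean	log_sd	lines (ppm:relative_intensity;...)
lactate	1	-0.6931	0.12	1.330:10;4.110:3
alanine	1	-0.6931	0.12	1.480:6;3.780:2
acetate	1	-0.6931	0.12	1.920:8
succinate	1	-0.6931	0.12	2.410:9
citrate	1	-0.6931	0.12	2.540:5;2.660:5
cis-aconitate	1	-0.6931	0.12	3.120:4;6.580:2
taurine	1	-0.6931	0.12	3.260:6;3.430:6
hippurate	1	-0.6931	0.12	3.970:2;7.550:3;7.640:1;7.830:2
creatinine	0	1.0986	0.10	3.050:9;4.060:3
creatine-phosphate	0	0.0	0.12	3.910:3
trimethylamine-N-oxide	0	0.0	0.12	3.310:8
dimethylamine	0	0.0	0.12	2.720:7
methylamine	0	0.0	0.12	2.610:5
trimethylamine	0	0.0	0.12	2.880:6
dimethylglycine	0	0.0	0.12	2.930:5
ethanol	0	0.0	0.12	1.180:6;3.660:2
2-hydroxybutyrate	0	0.0	0.12	0.900:5;2.000:2
isovalerate	0	0.0	0.12	0.940:6;2.060:2
dihydrothymine	0	0.0	0.12	1.120:4
methionine-sulfoxide	0	0.0	0.12	2.760:3
allantoin	0	0.0	0.12	5.230:3
trigonelline	0	0.0	0.12	4.430:2;8.080:1;9.120:2
n-methylnicotinamide	0	0.0	0.12	8.180:1;8.900:2
phenylacetylglycine	0	0.0	0.12	7.360:3;7.420:2
1-methylurate	0	0.0	0.12	3.390:2
glycolate	0	0.0	0.12	3.570:3
imidazole	0	0.0	0.12	7.160:2;8.260:1
benzoate	0	0.0	0.12	7.480:2
2-oxoisocaproate	0	0.0	0.12	2.100:2
formate	0	0.0	0.12	8.460:1
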