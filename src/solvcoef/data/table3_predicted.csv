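# Random-forest predicted zero-intercept Abraham coefficients for
# candidate sustainable solvents.
name,e0,s0,a0,b0,v0
"1,3-dioxan-5-ol",0.407,-0.238,-0.110,-3.616,3.523
"1,3-dioxolane",0.311,-0.233,-0.305,-4.661,4.029
"1,3-dioxolane-4-methanol",0.404,-0.250,-0.108,-3.641,3.528
"1,4-cineol",0.397,-0.616,-0.909,-4.718,4.299
"1,8-cineol",0.393,-0.581,-0.921,-4.723,4.316
"2-butoxy-1,3-propanediol",0.452,-0.493,-0.285,-3.531,3.826
2-furfuraldehyde,0.300,0.023,-0.539,-4.305,3.885
2-methyltetrahydrofuran,0.344,-0.557,-0.565,-4.686,4.440
2-pyrrolidone,0.306,0.011,0.734,-4.709,4.020
3-hydroxypropionic acid,0.324,-0.155,-0.180,-3.758,3.500
3-methoxy-3-methyl-1-butanol,0.310,-0.637,-0.200,-3.916,4.002
5-(hydroxymethyl)furfural,0.413,0.084,-0.314,-3.451,3.729
acetic acid,0.193,0.016,-0.103,-3.625,3.565
acetyl tributyl citrate,0.689,-0.837,-1.091,-4.415,3.969
alpha-pinene,0.544,-1.225,-3.200,-4.719,4.511
alpha-terpineol,0.410,-0.853,-0.527,-4.003,4.172
benzyl alcohol,0.365,-0.399,-0.381,-3.949,4.143
benzyl benzoate,0.483,-0.550,-1.155,-4.526,4.072
beta-farnesen,0.576,-1.418,-3.214,-4.852,4.470
beta-myrcene,0.572,-1.421,-3.173,-4.904,4.599
beta-pinene,0.543,-1.245,-3.217,-4.723,4.511
beta-terpineol,0.439,-0.807,-0.554,-4.038,4.158
butyl laurate,0.617,-0.934,-1.210,-4.578,4.108
butyl myristate,0.635,-0.922,-1.210,-4.541,4.108
butyl palmitate,0.623,-0.917,-1.210,-4.541,4.106
butyl stearate,0.615,-0.917,-1.208,-4.538,4.106
caprylic acid diethanolamide,0.476,-0.532,-0.279,-3.717,3.864
cyclademol,0.463,-1.076,-0.413,-4.012,4.182
cyclopentyl methyl ether,0.385,-0.387,-0.654,-4.717,4.470
decamethylcyclo-pentasiloxane,0.460,-0.728,-0.788,-4.318,3.963
dibutyl sebacate,0.680,-0.892,-1.239,-4.329,3.976
diethyl adipate,0.359,-0.384,-0.954,-4.515,4.025
diethyl glutarate,0.349,-0.308,-0.979,-4.477,4.021
diethyl phthalate,0.444,-0.397,-1.082,-4.412,4.016
diethyl succinate,0.354,-0.169,-0.897,-4.480,3.956
dihydromyrcenol,0.479,-1.150,-0.458,-4.025,4.272
diisoamylsuccinate,0.571,-0.700,-1.006,-4.286,3.973
diisobutyl adipate,0.464,-0.607,-0.997,-4.338,4.007
diisobutyl glutarate,0.481,-0.543,-1.019,-4.301,4.000
diisobutyl succinate,0.424,-0.430,-1.007,-4.326,3.982
diisooctyl succinate,0.711,-0.861,-1.127,-4.262,3.967
dimethyl 2-methylglutarate,0.344,-0.144,-0.783,-4.365,3.879
dimethyl adipate,0.345,-0.156,-0.875,-4.446,3.878
dimethyl glutarate,0.342,-0.099,-0.855,-4.422,3.849
dimethyl isosorbide,0.353,-0.132,-0.394,-4.083,3.587
dimethyl phthalate,0.411,-0.189,-1.005,-4.385,3.940
dimethyl succinate,0.337,0.063,-0.704,-4.430,3.830
dioctyl succinate,0.701,-0.891,-1.233,-4.298,3.966
dipropyleneglycol,0.392,-0.442,-0.225,-3.468,3.748
d-limonene,0.558,-1.298,-3.188,-4.832,4.527
ethyl lactate,0.242,-0.026,-0.412,-3.575,3.868
ethyl laurate,0.590,-0.902,-1.133,-4.660,4.124
ethyl linoleate,0.531,-0.837,-1.094,-4.519,4.129
ethyl linolenate,0.535,-0.838,-1.100,-4.522,4.135
ethyl myristate,0.601,-0.934,-1.168,-4.585,4.116
ethyl oleate,0.577,-0.885,-1.120,-4.520,4.114
ethyl palmitate,0.630,-0.922,-1.179,-4.544,4.111
ethylhexyllactate,0.515,-0.690,-0.821,-3.643,3.974
furfuryl alcohol,0.351,-0.195,-0.047,-3.553,3.880
gamma-valerolactone,0.293,0.151,-0.795,-4.521,3.957
geraniol,0.435,-0.953,-0.428,-4.113,4.238
geranyl acetate,0.517,-0.799,-1.124,-4.625,4.128
glycerol,0.405,-0.430,0.076,-3.421,3.476
glycerol carbonate,0.282,0.082,-0.587,-3.530,3.529
glycerol triacetate,0.325,-0.139,-0.913,-4.381,3.893
"glycerol-1,2,3-tributyl ether",0.542,-0.934,-0.994,-4.257,4.082
"glycerol-1,2,3-triethyl ether",0.370,-0.473,-0.778,-4.427,4.078
"glycerol-1,2,3-trimethyl ether",0.315,-0.358,-0.407,-4.280,3.931
"glycerol-1,2-dibutyl ether",0.437,-0.680,-0.624,-3.709,3.983
"glycerol-1,2-diethyl ether",0.361,-0.415,-0.244,-3.663,3.932
"glycerol-1,2-dimethyl ether",0.338,-0.410,-0.121,-3.525,3.663
"glycerol-1,3-Dibutyl ether",0.423,-0.658,-0.583,-3.592,4.001
"glycerol-1,3-diethyl ether",0.357,-0.398,-0.255,-3.555,3.864
"glycerol-1,3-dimethyl ether",0.324,-0.402,-0.131,-3.467,3.676
glycerol-1-ethyl monoether,0.424,-0.380,-0.172,-3.432,3.583
glycerol-1-methyl monoether,0.394,-0.376,-0.106,-3.403,3.510
glycerol-2-ethyl monoether,0.435,-0.400,-0.151,-3.430,3.579
glycerol-2-methyl monoether,0.403,-0.429,-0.108,-3.382,3.500
glycofurol (n = 2),0.479,-0.420,-0.427,-3.354,3.673
isoamyl acetate,0.310,-0.358,-0.830,-4.754,4.262
isobutyl acetate,0.251,-0.237,-0.798,-4.771,4.249
isododecane,0.631,-1.656,-3.473,-4.842,4.548
isopropyl palmitate,0.730,-0.984,-1.332,-4.354,4.040
isopropylacetate,0.232,-0.186,-0.803,-4.708,4.234
isosorbide dioctanoate,0.618,-0.827,-1.092,-4.216,3.888
menthanol,0.485,-1.103,-0.435,-4.031,4.184
menthanyl acetate,0.568,-0.685,-1.121,-4.472,4.094
menthyl acetate,0.566,-0.697,-1.117,-4.508,4.107
methyl 5-(dimethylamino) 2-methyl-oxopentanoate,0.323,-0.119,-0.405,-4.378,3.848
methyl abietate,0.635,-0.720,-1.152,-4.450,4.083
methyl laurate,0.535,-0.858,-1.071,-4.676,4.090
methyl linoleate,0.505,-0.806,-1.028,-4.524,4.081
methyl linolenate,0.510,-0.794,-1.023,-4.523,4.097
methyl myristate,0.583,-0.885,-1.110,-4.645,4.078
methyl oleate,0.572,-0.852,-1.072,-4.523,4.078
methyl palmitate,0.611,-0.890,-1.127,-4.578,4.076
methyl ricinoleate,0.578,-0.808,-0.890,-3.915,3.979
methyl stearate,0.591,-0.880,-1.121,-4.554,4.074
"N,N-diethylolcapramide",0.485,-0.640,-0.330,-3.718,3.857
"N,N-dimethyldecanamide",0.563,-0.767,-0.035,-4.812,4.103
"N,N-dimethyloctanamide",0.484,-0.549,-0.010,-4.843,4.121
nopol,0.365,-0.784,-0.385,-4.026,4.112
n-propyl acetate,0.299,-0.349,-0.738,-4.889,4.267
oleic acid,0.485,-0.817,-0.611,-4.106,4.042
p-cymene,0.564,-1.163,-3.112,-4.797,4.526
PEG 200,0.490,-0.423,-0.310,-3.297,3.495
PEG 600,0.469,-0.528,-0.309,-3.307,3.502
perfluorooctane,0.386,-0.813,-2.663,-4.033,4.079
propionic acid,0.207,-0.105,-0.185,-3.981,3.840
"1,2-propylene glycol",0.387,-0.447,0.259,-3.447,3.586
ricinoleic acid,0.477,-0.812,-0.787,-3.938,3.971
solketal,0.297,-0.208,-0.251,-3.678,3.789
terpineol acetate,0.470,-0.618,-1.089,-4.541,4.097
terpinolene,0.544,-1.209,-3.212,-4.860,4.535
tetrahydrofurfurylic alcohol,0.433,-0.365,-0.168,-3.544,3.857
tributyl citrate,0.572,-0.723,-0.887,-3.892,3.961
triethyl citrate,0.379,-0.317,-0.618,-3.835,3.826
trimethylene glycol,0.434,-0.627,0.236,-3.726,3.600
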