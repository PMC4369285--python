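# Measured Abraham solvent coefficients: original convention (c,e,s,a,b,v)
# paired with the zero-intercept recalibration (e0,s0,a0,b0,v0).
name,c,e,s,a,b,v,e0,s0,a0,b0,v0
methyl acetate,0.351,0.223,-0.150,-1.035,-4.527,3.972,0.195,-0.068,-0.924,-4.571,4.152
ethyl acetate,0.328,0.369,-0.446,-0.700,-4.904,4.150,0.343,-0.369,-0.597,-4.945,4.319
butyl acetate,0.248,0.356,-0.501,-0.867,-4.973,4.281,0.336,-0.443,-0.788,-5.005,4.409
isopropyl myristate,-0.605,0.930,-1.153,-1.682,-4.093,4.249,0.977,-1.295,-1.870,-4.018,3.939
N-methylacetamide,0.090,0.205,-0.172,1.305,-4.589,3.833,0.197,-0.151,1.335,-4.601,3.880
N-ethylacetamide,0.284,0.128,-0.442,1.180,-4.728,3.856,0.105,-0.375,1.269,-4.764,4.002
dimethylacetamide,-0.271,0.084,0.209,0.915,-5.003,4.557,0.105,0.145,0.832,-4.970,4.419
"N,N-diethylacetamide",0.213,0.034,0.089,1.342,-5.084,4.088,0.017,0.139,1.409,-5.111,4.198
formamide,-0.171,0.070,0.308,0.589,-3.152,2.432,0.083,0.268,0.537,-3.132,2.345
N-methylformamide,0.114,0.407,-0.287,0.542,-4.085,3.471,0.398,-0.260,0.579,-4.100,3.530
N-ethylformamide,0.220,0.034,-0.166,0.935,-4.589,3.730,0.016,-0.114,1.005,-4.617,3.843
DMF,-0.305,-0.058,0.343,0.358,-4.865,4.486,-0.034,0.271,0.264,-4.828,4.330
dibutylformamide,0.332,0.302,-0.436,0.358,-4.902,3.952,0.275,-0.358,0.462,-4.944,4.123
methanol,0.276,0.334,-0.714,0.243,-3.320,3.549,0.312,-0.649,0.330,-3.355,3.691
ethanol,0.222,0.471,-1.035,0.326,-3.596,3.857,0.453,-0.983,0.396,-3.623,3.971
ethanol/water(90:10)vol,0.243,0.213,-0.575,0.262,-3.450,3.545,0.193,-0.518,0.339,-3.481,3.670
ethanol/water(80:20)vol,0.172,0.175,-0.465,0.260,-3.212,3.323,0.161,-0.424,0.314,-3.233,3.411
ethanol/water(70:30)vol,0.063,0.085,-0.368,0.311,-2.936,3.102,0.079,-0.353,0.331,-2.944,3.134
ethanol/water(60:40)vol,-0.040,0.138,-0.335,0.293,-2.675,2.812,0.141,-0.344,0.281,-2.670,2.792
ethanol/water(50:50)vol,-0.142,0.124,-0.252,0.251,-2.275,2.415,0.135,-0.285,0.207,-2.257,2.342
ethanol/water(40:60)vol,-0.221,0.131,-0.159,0.171,-1.809,1.918,0.148,-0.211,0.103,-1.782,1.805
ethanol/water(30:70)vol,-0.269,0.107,-0.098,0.133,-1.316,1.414,0.128,-0.161,0.049,-1.283,1.276
ethanol/water(20:80)vol,-0.252,0.043,-0.040,0.096,-0.832,0.916,0.063,-0.099,0.017,-0.801,0.787
ethanol/water(10:90)vol,-0.173,-0.023,-0.001,0.065,-0.372,0.454,-0.009,-0.042,0.011,-0.350,0.365
water,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000
1-propanol,0.139,0.405,-1.029,0.247,-3.767,3.986,0.393,-0.996,0.291,-3.785,4.058
2-propanol,0.099,0.343,-1.049,0.406,-3.827,4.033,0.335,-1.026,0.438,-3.839,4.084
2-methyl-1-propanol,0.188,0.354,-1.127,0.016,-3.568,3.968,0.339,-1.083,0.076,-3.592,4.065
2-methyl-2-propanol,0.211,0.171,-0.947,0.331,-4.085,4.109,0.154,-0.897,0.398,-4.112,4.218
1-butanol,0.165,0.401,-1.011,0.056,-3.958,4.044,0.388,-0.972,0.108,-3.979,4.129
2-butanol,0.127,0.253,-0.976,0.158,-3.882,4.114,0.242,-0.946,0.199,-3.898,4.179
3-methyl-1-butanol,0.073,0.360,-1.273,0.090,-3.770,4.399,0.354,-1.256,0.113,-3.779,4.437
1-pentanol,0.150,0.536,-1.229,0.141,-3.864,4.077,0.524,-1.194,0.188,-3.883,4.154
2-pentanol,0.115,0.455,-1.331,0.206,-3.745,4.201,0.445,-1.304,0.243,-3.759,4.260
1-hexanol,0.115,0.492,-1.164,0.054,-3.978,4.131,0.483,-1.137,0.091,-3.993,4.191
1-heptanol,0.035,0.398,-1.063,0.002,-4.342,4.317,0.395,-1.055,0.014,-4.347,4.335
1-octanol,-0.034,0.489,-1.044,-0.024,-4.235,4.218,0.491,-1.052,-0.034,-4.231,4.201
1-decanol,-0.058,0.616,-1.319,0.026,-4.153,4.279,0.620,-1.333,0.009,-4.146,4.250
octadecanol,-0.096,0.148,-0.841,-0.438,-4.040,4.125,0.155,-0.864,-0.467,-4.028,4.076
pentane,0.369,0.386,-1.568,-3.535,-5.215,4.514,0.357,-1.481,-3.419,-5.261,4.704
hexane,0.333,0.560,-1.710,-3.578,-4.939,4.463,0.533,-1.632,-3.473,-4.981,4.634
heptane,0.297,0.643,-1.755,-3.571,-4.946,4.488,0.619,-1.685,-3.477,-4.983,4.641
octane,0.231,0.738,-1.840,-3.585,-4.907,4.502,0.719,-1.786,-3.512,-4.936,4.621
nonane,0.240,0.619,-1.713,-3.532,-4.921,4.482,0.600,-1.657,-3.457,-4.951,4.606
decane,0.186,0.722,-1.741,-3.449,-4.970,4.476,0.707,-1.697,-3.390,-4.993,4.572
undecane,0.058,0.603,-1.661,-3.421,-5.120,4.619,0.598,-1.647,-3.402,-5.128,4.649
dodecane,0.114,0.668,-1.644,-3.545,-5.006,4.459,0.659,-1.617,-3.509,-5.021,4.518
hexadecane,0.087,0.667,-1.617,-3.587,-4.869,4.433,0.660,-1.596,-3.560,-4.880,4.478
"2,2,4-trimethylpentane",0.320,0.511,-1.685,-3.687,-4.811,4.399,0.485,-1.610,-3.586,-4.851,4.564
"1,9-decadiene",0.104,0.615,-1.796,-3.070,-4.291,4.518,0.606,-1.771,-3.037,-4.304,4.572
1-hexadecene,0.116,0.706,-1.616,-3.181,-4.796,4.322,0.697,-1.589,-3.144,-4.811,4.382
"1,2-dichloroethane",0.183,0.294,-0.134,-2.801,-4.291,4.180,0.279,-0.091,-2.743,-4.314,4.274
1-chlorobutane,0.222,0.273,-0.569,-2.918,-4.883,4.456,0.255,-0.517,-2.848,-4.911,4.570
dichloromethane,0.319,0.102,-0.187,-3.058,-4.090,4.324,0.076,-0.112,-2.957,-4.130,4.488
chloroform,0.191,0.105,-0.403,-3.112,-3.514,4.395,0.089,-0.358,-3.051,-3.538,4.493
carbon tetrachloride,0.199,0.523,-1.159,-3.560,-4.594,4.618,0.507,-1.112,-3.497,-4.619,4.721
trifluoroethanol,0.395,-0.094,-0.594,-1.280,-1.274,3.088,-0.126,-0.501,-1.156,-1.323,3.291
diethyl ether,0.350,0.358,-0.820,-0.588,-4.956,4.350,0.330,-0.737,-0.478,-5.000,4.530
dibutyl ether,0.176,0.394,-0.985,-1.414,-5.357,4.524,0.380,-0.944,-1.358,-5.379,4.615
methyl tert-butyl ether,0.341,0.307,-0.817,-0.618,-5.097,4.425,0.280,-0.737,-0.510,-5.140,4.600
benzene,0.142,0.464,-0.588,-3.009,-4.625,4.491,0.452,-0.554,-2.964,-4.643,4.564
fluorobenzene,0.139,0.152,-0.374,-3.030,-4.601,4.540,0.140,-0.341,-2.985,-4.618,4.611
chlorobenzene,0.065,0.381,-0.521,-3.183,-4.700,4.614,0.375,-0.506,-3.161,-4.708,4.648
bromobenzene,-0.017,0.436,-0.424,-3.174,-4.558,4.445,0.437,-0.428,-3.178,-4.556,4.437
iodobenzene,-0.192,0.298,-0.308,-3.213,-4.653,4.588,0.313,-0.353,-3.272,-4.629,4.490
toluene,0.125,0.431,-0.644,-3.002,-4.748,4.524,0.421,-0.615,-2.962,-4.764,4.589
ethylbenzene,0.093,0.467,-0.723,-3.001,-4.844,4.514,0.459,-0.701,-2.971,-4.856,4.562
m-xylene,0.122,0.377,-0.603,-2.981,-4.961,4.535,0.367,-0.574,-2.941,-4.977,4.598
o-xylene,0.083,0.518,-0.813,-2.884,-4.821,4.559,0.511,-0.793,-2.857,-4.831,4.602
p-xylene,0.166,0.477,-0.812,-2.939,-4.874,4.532,0.463,-0.773,-2.886,-4.895,4.618
nitrobenzene,-0.196,0.537,0.042,-2.328,-4.608,4.314,0.552,-0.004,-2.388,-4.584,4.214
cyclohexane,0.159,0.784,-1.678,-3.740,-4.929,4.577,0.771,-1.640,-3.689,-4.949,4.659
nitromethane,0.023,-0.091,0.793,-1.463,-4.364,3.460,-0.093,0.799,-1.454,-4.368,3.472
methylcyclohexane,0.246,0.782,-1.982,-3.517,-4.293,4.528,0.762,-1.924,-3.439,-4.324,4.655
THF,0.223,0.363,-0.384,-0.238,-4.932,4.450,0.345,-0.332,-0.167,-4.960,4.565
"1,4-dioxane",0.123,0.347,-0.033,-0.582,-4.810,4.110,0.337,-0.004,-0.542,-4.826,4.173
propylene carbonate,0.004,0.168,0.504,-1.283,-4.407,3.421,0.167,0.505,-1.281,-4.408,3.423
cyclohexanone,0.038,0.225,0.058,-0.976,-4.842,4.315,0.222,0.067,-0.963,-4.847,4.335
N-methylpyrrolidinone,0.147,0.532,0.225,0.840,-4.794,3.674,0.520,0.260,0.887,-4.813,3.750
N-methyl-2-piperidone,0.056,0.332,0.257,1.556,-5.035,3.983,0.327,0.271,1.575,-5.044,4.012
N-formylmorpholine,-0.032,0.696,-0.062,0.014,-4.092,3.405,0.698,-0.069,0.005,-4.089,3.389
benzonitrile,0.097,0.285,0.059,-1.605,-4.562,4.028,0.277,0.082,-1.574,-4.575,4.078
acetonitrile,0.413,0.077,0.326,-1.566,-4.391,3.364,0.044,0.423,-1.436,-4.443,3.576
ethylene glycol,-0.270,0.578,-0.511,0.715,-2.619,2.729,0.599,-0.575,0.631,-2.585,2.591
acetone,0.313,0.312,-0.121,-0.608,-4.753,3.942,0.287,-0.047,-0.509,-4.792,4.103
butanone,0.246,0.256,-0.080,-0.767,-4.855,4.148,0.236,-0.022,-0.689,-4.886,4.275
DMSO,-0.194,0.327,0.791,1.260,-4.540,3.361,0.342,0.746,1.200,-4.517,3.262
carbon disulfide,0.047,0.686,-0.943,-3.603,-5.818,4.921,0.682,-0.932,-3.587,-5.825,4.946
sulfolane,0.000,0.147,0.601,-0.381,-4.541,3.290,0.147,0.601,-0.380,-4.542,3.290
tributyl phosphate,0.022,0.350,-0.432,0.708,-4.725,4.192,0.544,-0.761,-0.966,-4.374,4.087
peanut oil,0.574,0.715,-1.027,-1.296,-4.512,3.446,0.670,-0.892,-1.121,-4.582,3.744
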