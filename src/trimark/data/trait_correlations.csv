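1.0,0.726,0.224,0.567,-0.358,0.574,0.268,0.26,0.179,-0.107,0.053,0.076,-0.491,-0.466,0.095
0.726,1.0,0.249,0.582,-0.398,0.634,0.391,0.393,0.111,-0.13,0.095,0.125,-0.414,0.353,0.171
0.224,0.249,1.0,0.261,-0.394,0.398,0.509,0.501,0.074,0.098,0.049,0.058,-0.053,-0.017,0.005
0.567,0.582,0.261,1.0,-0.564,0.571,0.46,0.428,0.159,-0.013,0.014,0.055,-0.322,-0.301,-0.015
-0.358,-0.398,-0.394,-0.564,1.0,-0.469,-0.52,-0.519,-0.024,0.156,0.222,0.115,0.152,0.116,0.156
0.574,0.634,0.398,0.571,-0.469,1.0,0.554,0.545,0.147,-0.116,-0.037,-0.054,-0.268,-0.24,0.104
0.268,0.391,0.509,0.46,-0.52,0.554,1.0,0.984,-0.272,0.085,-0.014,0.031,-0.158,-0.116,-0.047
0.26,0.393,0.501,0.428,-0.519,0.545,0.984,1.0,-0.25,0.067,-0.022,0.065,-0.14,-0.099,-0.084
0.179,0.111,0.074,0.159,-0.024,0.147,-0.272,-0.25,1.0,0.078,0.012,-0.045,0.145,0.036,-0.042
-0.107,-0.13,0.098,-0.013,0.156,-0.116,0.085,0.067,0.078,1.0,0.336,0.155,0.077,-0.143,0.001
0.053,0.095,0.049,0.014,0.222,-0.037,-0.014,-0.022,0.012,0.336,1.0,0.68,-0.239,-0.295,0.36
0.076,0.125,0.058,0.055,0.115,-0.054,0.031,0.065,-0.045,0.155,0.68,1.0,-0.27,-0.208,0.134
-0.491,-0.414,-0.053,-0.322,0.152,-0.268,-0.158,-0.14,0.145,0.077,-0.239,-0.27,1.0,0.891,-0.604
-0.466,0.353,-0.017,-0.301,0.116,-0.24,-0.116,-0.099,0.036,-0.143,-0.295,-0.208,0.891,1.0,-0.518
0.095,0.171,0.005,-0.015,0.156,0.104,-0.047,-0.084,-0.042,0.001,0.36,0.134,-0.604,-0.518,1.0
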