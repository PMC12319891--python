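label,x,y,z
Fp1,-0.270218,0.896322,-0.351552
Fpz,-0.005972,0.950882,-0.309495
Fp2,0.258925,0.900092,-0.350416
AF7,-0.504873,0.770337,-0.389466
AF3,-0.345025,0.932018,-0.110908
AFz,-0.005536,0.999472,0.032027
AF4,0.346597,0.932378,-0.102671
AF8,0.496478,0.776060,-0.388897
F7,-0.696218,0.575837,-0.428593
F5,-0.702294,0.692348,-0.165643
F3,-0.588474,0.800435,0.114030
F1,-0.339185,0.878505,0.336427
Fz,-0.005554,0.909616,0.415413
F2,0.342942,0.881382,0.324896
F4,0.583415,0.806339,0.097185
F6,0.702622,0.691737,-0.166801
F8,0.693190,0.582153,-0.424955
FT7,-0.838366,0.312504,-0.446637
FC5,-0.908857,0.406959,-0.091455
FC3,-0.802032,0.513080,0.305766
FC1,-0.479583,0.582243,0.656501
FCz,-0.005508,0.612439,0.790499
FC2,0.474277,0.595556,0.648363
FC4,0.799013,0.519456,0.302892
FC6,0.904861,0.415997,-0.090402
FT8,0.832521,0.325548,-0.448249
T7,-0.897830,0.002715,-0.440334
C5,-0.998767,0.031002,-0.038783
C3,-0.898080,0.063068,0.435287
C1,-0.538457,0.091743,0.837644
Cz,-0.005386,0.104065,0.994556
C2,0.546859,0.098566,0.831402
C4,0.902138,0.073086,0.425211
C6,0.998406,0.042251,-0.037421
T8,0.895866,0.013338,-0.444125
TP7,-0.866385,-0.301074,-0.398412
CP5,-0.935676,-0.352506,-0.015814
CP3,-0.817439,-0.390557,0.423388
CP1,-0.478043,-0.408666,0.777475
CPz,-0.005179,-0.419741,0.907629
CP2,0.495084,-0.405354,0.768492
CP4,0.825348,-0.380587,0.417078
CP6,0.940425,-0.339769,-0.012545
TP8,0.865297,-0.298739,-0.402511
P9,-0.620840,-0.483778,-0.616861
P7,-0.738012,-0.576444,-0.350785
P5,-0.749252,-0.660873,-0.043223
P3,-0.626909,-0.728753,0.275506
P1,-0.355046,-0.776188,0.521033
Pz,-0.005411,-0.790066,0.612998
P2,0.370591,-0.763902,0.528315
P4,0.634693,-0.720095,0.280406
P6,0.746766,-0.663431,-0.046910
P8,0.735285,-0.577682,-0.354457
P10,0.615156,-0.488878,-0.618532
PO7,-0.541006,-0.790481,-0.287145
PO3,-0.402782,-0.913789,0.052506
POz,-0.006298,-0.978032,0.208361
PO4,0.391389,-0.919151,0.044448
PO8,0.535586,-0.793651,-0.288557
O1,-0.291632,-0.929264,-0.226759
Oz,-0.006600,-0.984337,-0.176175
O2,0.282510,-0.931672,-0.228420
Iz,-0.006570,-0.879351,-0.476129
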