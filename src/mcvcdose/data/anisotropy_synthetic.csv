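r_cm,0,10,20,30,40,50,60,70,80,90,100,110,120,130,140,150,160,170,180
0.25,0.644000,0.653676,0.681709,0.725207,0.779653,0.839316,0.897766,0.948389,0.984765,1.000000,0.984765,0.948389,0.897766,0.839316,0.779653,0.725207,0.681709,0.653676,0.644000
0.5,0.686667,0.695183,0.719856,0.758141,0.806062,0.858574,0.910019,0.954575,0.986590,1.000000,0.986590,0.954575,0.910019,0.858574,0.806062,0.758141,0.719856,0.695183,0.686667
0.75,0.717143,0.724831,0.747104,0.781666,0.824925,0.872330,0.918771,0.958993,0.987895,1.000000,0.987895,0.958993,0.918771,0.872330,0.824925,0.781666,0.747104,0.724831,0.717143
1,0.740000,0.747067,0.767540,0.799309,0.839072,0.882647,0.925335,0.962307,0.988873,1.000000,0.988873,0.962307,0.925335,0.882647,0.839072,0.799309,0.767540,0.747067,0.740000
1.5,0.772000,0.778197,0.796151,0.824009,0.858879,0.897090,0.934524,0.966946,0.990242,1.000000,0.990242,0.966946,0.934524,0.897090,0.858879,0.824009,0.796151,0.778197,0.772000
2,0.793333,0.798950,0.815224,0.840476,0.872083,0.906719,0.940651,0.970039,0.991155,1.000000,0.991155,0.970039,0.940651,0.906719,0.872083,0.840476,0.815224,0.798950,0.793333
3,0.820000,0.824892,0.839066,0.861060,0.888589,0.918755,0.948309,0.973905,0.992297,1.000000,0.992297,0.973905,0.948309,0.918755,0.888589,0.861060,0.839066,0.824892,0.820000
5,0.846667,0.850834,0.862908,0.881644,0.905094,0.930792,0.955967,0.977771,0.993438,1.000000,0.993438,0.977771,0.955967,0.930792,0.905094,0.881644,0.862908,0.850834,0.846667
7.5,0.862353,0.866094,0.876933,0.893752,0.914803,0.937872,0.960471,0.980045,0.994109,1.000000,0.994109,0.980045,0.960471,0.937872,0.914803,0.893752,0.876933,0.866094,0.862353
10,0.870909,0.874418,0.884583,0.900356,0.920099,0.941734,0.962928,0.981285,0.994475,1.000000,0.994475,0.981285,0.962928,0.941734,0.920099,0.900356,0.884583,0.874418,0.870909
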