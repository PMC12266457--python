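epoch,loss,accuracy,iou,val_loss,val_accuracy,val_iou,lr,checkpoint
1,1.1988441869616508,0.7646989493534483,0.0417909424388906,0.45402584473292035,0.8506130642361112,0.03841452767592107,0.005,True
2,0.5146474689245224,0.8134933997844828,0.050488599348534204,0.30101772646109265,0.8788248697916666,0.0,0.005,False
3,0.3770005442202091,0.8288910964439655,9.839130220888473e-05,0.26056591007444596,0.8788248697916666,0.0,0.005,False
4,0.31259178183972836,0.829034213362069,0.0,0.25308313137955135,0.8788248697916666,0.0,0.005,False
5,0.30657541938126087,0.829034213362069,0.0,0.2313660623298751,0.8788248697916666,0.0,0.005,False
6,0.29996124655008316,0.829034213362069,0.0,0.22207342584927878,0.8788248697916666,0.0,0.005,False
7,0.2832887638360262,0.829034213362069,0.0,0.2197018704480595,0.8788248697916666,0.0,0.005,False
8,0.2544175647199154,0.829034213362069,0.0,0.21461033324400583,0.8788248697916666,0.0,0.005,False
9,0.2711150646209717,0.8337149784482759,0.03719229831830368,0.20925557447804344,0.9180772569444444,0.41038656774697385,0.005,True
10,0.24368437565863132,0.9002727640086207,0.5146474372106363,0.20408548331922954,0.9315321180555556,0.5145220234660511,0.005,True
11,0.28592891059815884,0.9078832165948276,0.5607210245292866,0.19838883148299324,0.9341091579861112,0.536007640878701,0.005,True
12,0.2528536096215248,0.9109728582974138,0.5787356092897263,0.19338671697510612,0.9360894097222222,0.5528563294742835,0.005,True
13,0.24913474917411804,0.9131617052801724,0.5914689690680819,0.1884397649102741,0.9375,0.5644612476370511,0.005,True
14,0.2508753817528486,0.9144918507543104,0.5989496959646213,0.1827070059047805,0.9408908420138888,0.5912586756706059,0.005,True
15,0.22466805763542652,0.9175730738146551,0.6174195060956549,0.175902691980203,0.9425184461805556,0.6039992524761727,0.005,True
16,0.21229824982583523,0.9194167564655172,0.628069630090146,0.16852515935897827,0.9442003038194444,0.6185796402744298,0.005,True
17,0.22735068388283253,0.9222706761853449,0.6414368932038835,0.15721754315826628,0.9590657552083334,0.6882875438958893,0.005,True
18,0.1996543649584055,0.9372979525862069,0.6775338788587263,0.15554065836800468,0.9609375,0.6999374869764534,0.005,True
19,0.1769458968192339,0.9504647090517241,0.7408157871553167,0.12670861764086616,0.9644911024305556,0.7265510758303739,0.005,True
20,0.1453711837530136,0.9552464978448276,0.7662166322177756,0.09810657468107012,0.9680718315972222,0.7634170854271357,0.005,True
21,0.1252646092325449,0.9555916621767241,0.7715065407606342,0.09216604299015468,0.9665798611111112,0.7424749163879598,0.005,False
22,0.1633984474465251,0.9573343211206896,0.7776217639315489,0.09228208247158262,0.9648980034722222,0.7260215964429388,0.005,False
23,0.12927205581218004,0.9519800646551724,0.7422503389064619,0.0983908043967353,0.966796875,0.7411714950306618,0.005,False
24,0.12441800255328417,0.9596578663793104,0.7883953015985163,0.08392785158422258,0.9679633246527778,0.7535989985395368,0.005,False
25,0.11043842695653439,0.9608869881465517,0.7954475410557831,0.0814607838789622,0.9681803385416666,0.7539332913782253,0.005,False
26,0.10236443765461445,0.9626296470905172,0.8039137733015284,0.06778843783670002,0.9730902777777778,0.790584758285835,0.005,True
27,0.09440699638798833,0.9661823141163793,0.8207576636473161,0.06185092031955719,0.9777289496527778,0.8265370800760617,0.005,True
28,0.09301518741995096,0.9675629714439655,0.8277603933839964,0.056896758990155324,0.9825846354166666,0.8646140868831717,0.005,True
29,0.08511785743758082,0.968194369612069,0.8313016298280866,0.0532075199815962,0.9832899305555556,0.8702611625947767,0.005,True
30,0.08337262459099293,0.968682650862069,0.8332885184189298,0.050141563846005335,0.9859754774305556,0.8914777497900923,0.005,True
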