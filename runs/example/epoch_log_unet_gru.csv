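epoch,loss,accuracy,iou,val_loss,val_accuracy,val_iou,lr,checkpoint
1,0.6549289748072624,0.7205010775862069,0.05007153075822604,0.6184706423017714,0.8788248697916666,0.0,0.005,True
2,0.5478714592754841,0.8289416082974138,9.842035332906845e-05,0.36629465884632534,0.8788248697916666,0.0,0.005,False
3,0.40444692596793175,0.8290089574353449,0.0001476814019887762,0.2823869172069762,0.8788248697916666,0.0,0.005,False
4,0.3142351694405079,0.829034213362069,0.0,0.23683124449517992,0.8788248697916666,0.0,0.005,False
5,0.26958688721060753,0.829034213362069,0.0,0.22530841496255663,0.8788248697916666,0.0,0.005,False
6,0.252290777862072,0.8290426320043104,4.924167815639157e-05,0.20495821121666166,0.8788248697916666,0.0,0.005,False
7,0.2550991717725992,0.8291268184267241,0.0018686992869436931,0.2075306549668312,0.8797200520833334,0.007831729693443723,0.005,True
8,0.2330194115638733,0.8373602505387931,0.05636692228789137,0.1848603164156278,0.9008246527777778,0.19329214474845544,0.005,True
9,0.2266911044716835,0.8871228448275862,0.3718435230733193,0.16795507238970864,0.9420301649305556,0.5906914384217583,0.005,True
10,0.2100398652255535,0.9229778421336207,0.6299247633686595,0.14900040957662794,0.9460177951388888,0.6345270890725436,0.005,True
11,0.1833420181646943,0.9233650996767241,0.6470063595470762,0.13363028979963726,0.9437934027777778,0.6318407960199005,0.005,False
12,0.17526916321367025,0.9281300511853449,0.6643073414336833,0.11850991100072861,0.9615071614583334,0.7158021229721611,0.005,True
13,0.1390518555417657,0.9510876885775862,0.7474901125646486,0.1229943831761678,0.9589301215277778,0.6821331093848415,0.005,False
14,0.1410292647778988,0.9508519665948276,0.7402678293366552,0.10049156844615936,0.9626736111111112,0.7226365652086273,0.005,True
15,0.11757884826511145,0.956475619612069,0.7698232491874806,0.09999834580553903,0.9633517795138888,0.7120630861040068,0.005,False
16,0.11910856142640114,0.9556590113146551,0.7622980413394711,0.08385174887047873,0.9661187065972222,0.7385935537881959,0.005,True
17,0.1064715851098299,0.9573511584051724,0.773960378368731,0.08177919271919462,0.9652506510416666,0.7365281777046483,0.005,False
18,0.10084879258647561,0.9574437634698276,0.7729620480574894,0.07899268633789486,0.9662814670138888,0.7406634675568537,0.005,True
19,0.1097876988351345,0.9572585533405172,0.7713063063063063,0.07635952449507183,0.9670138888888888,0.7514309076042518,0.005,True
20,0.09850521292537451,0.958807583512931,0.7831981922105543,0.0717485286295414,0.96826171875,0.758364312267658,0.005,True
21,0.09526707464829087,0.9595905172413793,0.7855611150822016,0.07079743055833711,0.9685872395833334,0.7560564567095007,0.005,False
22,0.09202412003651261,0.9603145204741379,0.7879823693442476,0.06660573846764034,0.9695638020833334,0.7652719665271966,0.005,True
23,0.09998084045946598,0.9627306707974138,0.8026919819940277,0.06425401858157581,0.9721950954861112,0.785475094181666,0.005,True
24,0.08462193002924323,0.9661907327586207,0.8205219878441187,0.06353711585203807,0.9750434027777778,0.8065194532071503,0.005,True
25,0.08430640446022153,0.966973666487069,0.8246547177401332,0.058963972247309156,0.9799262152777778,0.845865444699021,0.005,True
26,0.08273099083453417,0.970635775862069,0.8447431674530401,0.0562191651099258,0.9830729166666666,0.86926461345066,0.005,True
27,0.08665006794035435,0.9725215517241379,0.8544286861118544,0.051599154248833656,0.9844021267361112,0.8797071129707112,0.005,True
28,0.08526728907600045,0.9733465786637931,0.8581286968990859,0.0469086981481976,0.9862467447916666,0.8937552388935457,0.005,True
29,0.07275097724050283,0.9751818426724138,0.8682281423207581,0.045514697002040014,0.9872504340277778,0.9017763845350052,0.005,True
30,0.06687684473581612,0.9761078933189655,0.8730939498278406,0.04355520403219594,0.9875217013888888,0.9035639412997903,0.005,True
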