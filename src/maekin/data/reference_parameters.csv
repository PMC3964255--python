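model,factor,level,y_max,k_m,tau,gof_printed
first_order,power,250,0.013715,0.094507,,0.084504
first_order,power,350,0.568469,0.069558,,0.018957
first_order,power,450,0.622861,0.069927,,0.018408
first_order,power,500,0.643451,0.065034,,0.051907
first_order,power,550,0.718277,0.073040,,0.052717
first_order,ethanol,50,0.754853,0.073097,,0.052993
first_order,ethanol,60,0.761361,0.072713,,0.052911
first_order,ethanol,70,0.804594,0.072975,,0.052548
first_order,ethanol,80,0.890682,0.073307,,0.052608
first_order,ethanol,90,0.831694,0.073287,,0.053215
first_order,ethanol,100,0.718277,0.073040,,0.052717
first_order,preleach,1,1.083663,0.072867,,0.052288
first_order,preleach,5,1.102309,0.073028,,0.052639
first_order,preleach,10,1.105546,0.072777,,0.052213
first_order,preleach,15,1.107016,0.072974,,0.052566
first_order,preleach,20,1.127495,0.072855,,0.052249
first_order,preleach,25,1.129510,0.072919,,0.052386
first_order,preleach,30,1.133223,0.072485,,0.052057
logistic,power,250,0.013716,0.013716,9.078383,0.064274
logistic,power,350,0.558402,0.156855,11.625592,0.040377
logistic,power,450,0.611637,0.158482,11.513974,0.040776
logistic,power,500,0.636598,0.121393,12.340408,0.023855
logistic,power,550,0.713695,0.125821,10.917342,0.021411
logistic,ethanol,50,0.749934,0.126824,10.938109,0.022006
logistic,ethanol,60,0.756452,0.125319,10.962490,0.021600
logistic,ethanol,70,0.799469,0.125387,10.909826,0.021116
logistic,ethanol,80,0.885108,0.126128,10.886925,0.021164
logistic,ethanol,90,0.826444,0.126240,10.884430,0.021859
logistic,ethanol,100,0.713695,0.125821,10.917342,0.021411
logistic,preleach,1,1.076805,0.125075,10.928752,0.020460
logistic,preleach,5,1.095355,0.125485,10.911725,0.020907
logistic,preleach,10,1.098343,0.125436,10.941557,0.020672
logistic,preleach,15,1.100119,0.125104,10.919032,0.020930
logistic,preleach,20,1.120260,0.124949,10.905220,0.020455
logistic,preleach,25,1.122212,0.125592,10.921825,0.021031
logistic,preleach,30,1.126029,0.124124,10.972533,0.020265
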