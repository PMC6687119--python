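condition,parameter,family,c0,c1,c2,c3,casr_lo,casr_hi
control,p_scr,logistic_inc,0.9125001695991849,0.0010994787511205998,0.0,0.0,0.9,1.3
control,ti_sep,sigmoid_dec,69.16337272605386,14611.60886995342,0.8623520330363441,0.027920327833486087,0.9,1.3
control,md,sigmoid_dec,89.00000000025068,44.99999999984,1.0498909905748204,0.0002688484083648214,0.9,1.3
control,k_f1,sigmoid_dec,6.997284832968557,1476.0047534463695,0.8411065682526759,0.03727129205565153,0.9,1.3
control,k_f2,sigmoid_dec,15.76901423957415,69.63231783774428,0.9752610383495033,0.0011431367448992407,0.9,1.3
control,dw1,sigmoid_dec,6.407328712542215,52.413694639745955,0.999893512878342,0.00010955626129281243,0.9,1.3
control,dw2,sigmoid_dec,7.854398269737525,42.07533801665575,1.0000126129475604,0.00010585360950732869,0.9,1.3
control,cf_ti_sep,constant,0.41476582501867176,0.0,0.0,0.0,0.9,1.3
r_cru_cru,p_scr,logistic_inc,0.9220392733396071,0.001005531675544605,0.0,0.0,0.9,1.3
r_cru_cru,ti_sep,sigmoid_dec,55.923110824295065,12384.306722541705,0.8494221298635883,0.03382537219897641,0.9,1.3
r_cru_cru,md,sigmoid_dec,80.0444020401989,1370.9999999999998,0.867579084796392,0.025657119543089777,0.9,1.3
r_cru_cru,k_f1,sigmoid_dec,7.646935768658464,1017.7346707790743,0.8169784014508719,0.04658953399063353,0.9,1.3
r_cru_cru,k_f2,sigmoid_dec,11.377647481390085,1916.3341031097468,0.8623335316670963,0.027913481987764423,0.9,1.3
r_cru_cru,dw1,sigmoid_dec,5.014765050860402,619.234217296551,0.8952615311509579,0.013071678230401337,0.9,1.3
r_cru_cru,dw2,sigmoid_dec,7.255786384706928,628.1542057999327,0.8904356034970017,0.015265504272257016,0.9,1.3
r_cru_cru,cf_ti_sep,constant,0.35823506385445886,0.0,0.0,0.0,0.9,1.3
r_serca_ncx,p_scr,logistic_inc,0.9125001695991849,0.0010994787511205998,0.0,0.0,0.9,1.3
r_serca_ncx,ti_sep,sigmoid_dec,51.44896427275438,14122.92148615571,0.8586092851294417,0.029883349521460777,0.9,1.3
r_serca_ncx,md,sigmoid_dec,90.00000023613369,49.99999963223615,1.0481925135212262,0.0023979213982570614,0.9,1.3
r_serca_ncx,k_f1,sigmoid_dec,7.1772557505805725,212.54031696077726,0.9395837120743269,0.016751869277631726,0.9,1.3
r_serca_ncx,k_f2,sigmoid_dec,7.517587010266882,1557.3588488555554,0.8233673377733196,0.04546194385740833,0.9,1.3
r_serca_ncx,dw1,sigmoid_dec,6.412283384884465,58.93360484409436,0.9939882930929016,0.0068438144577629345,0.9,1.3
r_serca_ncx,dw2,sigmoid_dec,5.900685286624719,55.43777853241889,1.0229697903523114,0.0179852639982848,0.9,1.3
r_serca_ncx,cf_ti_sep,constant,0.3448801483823236,0.0,0.0,0.0,0.9,1.3
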