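variety,date,P,I,ET,D,R,Qi,Qo,dS
kantana,2017-12-14,26,0,13,0,0,315,328,-14
kantana,2017-12-22,28,0,7,0,0,328,350,-21
kantana,2017-12-29,15,0,13,0,0,350,352,-2
kantana,2018-01-05,7,10,29,0,0,352,340,12
kantana,2018-01-12,11,23,50,0,0,340,323,17
kantana,2018-01-19,26,46,55,0,0,323,339,-17
kantana,2018-01-31,34,39,81,0,0,339,331,8
kantana,2018-02-05,12,37,45,0,0,331,336,-4
kantana,2018-02-18,79,46,87,28,0,336,345,-10
kantana,2018-03-05,15,60,81,6,0,345,334,12
kantana,2018-03-10,3,31,31,1,0,334,336,-2
kantana,2018-03-16,2,59,40,1,0,336,357,-21
kantana,2018-03-24,209,0,44,88,0,357,434,-77
kantana,2018-04-02,8,38,40,34,0,434,406,29
kantana,2018-04-08,1,16,28,3,0,406,391,14
kantana,2018-04-14,64,0,25,17,0,391,413,-22
kangara,2017-12-14,26,0,14,0,0,264,276,-13
kangara,2017-12-22,28,28,8,0,0,276,324,-48
kangara,2017-12-29,15,4,12,0,0,324,332,-8
kangara,2018-01-05,7,8,23,0,0,332,324,8
kangara,2018-01-12,11,31,47,0,0,324,319,5
kangara,2018-01-19,26,40,54,0,0,319,332,-12
kangara,2018-01-31,34,72,81,0,0,332,356,-25
kangara,2018-02-05,12,50,36,0,0,356,383,-27
kangara,2018-02-18,79,0,87,19,0,383,355,27
kangara,2018-03-05,15,81,81,7,0,355,363,-8
kangara,2018-03-10,3,63,31,0,0,363,398,-34
kangara,2018-03-16,2,60,40,1,0,398,420,-22
kangara,2018-03-24,209,0,44,64,0,420,521,-101
kangara,2018-04-02,8,0,41,53,0,521,435,86
agrigreen,2017-12-14,26,0,12,0,0,292,306,-14
agrigreen,2017-12-22,28,0,7,0,0,306,327,-21
agrigreen,2017-12-29,15,0,18,1,0,327,322,4
agrigreen,2018-01-05,7,0,38,1,0,322,290,32
agrigreen,2018-01-12,11,40,50,0,0,290,291,-1
agrigreen,2018-01-19,26,51,54,0,0,291,314,-23
agrigreen,2018-01-31,34,71,81,8,0,314,330,-16
agrigreen,2018-02-05,12,60,36,4,0,330,363,-32
agrigreen,2018-02-18,79,42,89,28,0,363,366,-3
agrigreen,2018-03-05,15,66,84,6,0,366,357,9
agrigreen,2018-03-10,3,52,31,1,0,357,380,-23
agrigreen,2018-03-16,2,52,39,1,0,380,395,-14
agrigreen,2018-03-24,209,0,45,51,0,395,508,-113
agrigreen,2018-04-02,8,24,41,29,0,508,470,38
agrigreen,2018-04-08,1,0,28,3,0,470,440,30
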