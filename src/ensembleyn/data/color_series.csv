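family,level,x,y,Y,L,a,b,R,G,B,hex
green,1,0.322,0.498,10.759,39.172,-28.659,29.259,62,105,40,#3E6928
green,2,0.324,0.496,16.090,47.092,-31.958,33.359,77,128,51,#4D8033
green,3,0.326,0.492,23.511,55.595,-34.968,37.306,95,155,63,#5F9B3F
green,4,0.325,0.488,32.637,63.866,-36.799,38.568,113,184,76,#71B84C
green,5,0.323,0.491,47.588,74.564,-45.063,46.344,132,213,90,#84D55A
green,6,0.320,0.493,60.685,82.209,-50.536,50.183,146,236,100,#92EC64
green,7,0.320,0.492,70.950,87.461,-52.972,52.558,158,254,108,#9EFE6C
blue,1,0.220,0.188,1.416,12.064,8.684,-20.551,25,30,61,#191E3D
blue,2,0.217,0.189,6.141,29.765,12.824,-33.442,58,67,124,#3A437C
blue,3,0.219,0.194,10.006,37.853,13.698,-37.276,74,85,155,#4A559B
blue,4,0.221,0.198,14.833,45.405,14.564,-41.460,90,103,185,#5A67B9
blue,5,0.219,0.195,20.207,52.070,16.783,-47.263,105,120,214,#6978D6
blue,6,0.218,0.193,25.237,57.306,18.712,-51.811,118,135,239,#7687EF
blue,7,0.218,0.193,28.784,60.591,19.551,-54.133,126,143,253,#7E8FFD
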