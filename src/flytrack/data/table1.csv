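individual_id,site,group,sex,n_winter_sites,winter_duration_days,n_spring_stopovers,spring_duration_days,spring_distance_km,spring_rate_km_per_day,spring_stopover_days,spring_initiation,spring_arrival
1,RED,austral,F,2,169,5,45,4353,96.7,38,2011-08-29,2011-10-12
2,RED,austral,F,1,133,0,18,2922,162.3,0,2010-09-23,2010-10-10
3,RED,austral,F,2,183,1,,4816,,5,2014-09-27,
4,RED,austral,F,3,177,3,27,4555,168.7,18,2015-09-21,2015-10-17
5,RED,austral,M,2,182,4,43,3979,92.5,23,2011-08-30,2011-10-11
6,RED,austral,M,2,137,5,51,4705,92.3,42,2011-08-13,2011-10-02
7,RED,austral,M,2,126,3,36,4259,118.3,30,2010-09-08,2010-10-13
8,RED,austral,M,2,185,3,32,4618,144.3,11,2014-09-09,2014-10-10
9,RED,austral,M,2,142,4,21,4682,223.0,15,2014-09-15,2014-10-05
10,RPL,austral,F,4,155,2,31,4926,158.9,25,2014-09-05,2014-10-05
11,RPL,austral,F,2,131,2,57,4644,81.5,47,2014-08-29,2014-10-24
12,RPL,austral,M,3,152,4,29,4896,168.8,17,2014-09-12,2014-10-10
13,RPL,austral,M,1,158,3,40,4383,109.6,28,2014-08-30,2014-10-08
14,RPL,austral,M,5,151,1,23,3311,143.9,2,2014-09-29,2014-10-21
15,RPL,austral,M,2,147,2,47,4351,92.6,29,2014-08-30,2014-10-15
16,RPL,austral,M,1,128,2,29,4918,169.6,21,2014-09-07,2014-10-05
17,RPL,austral,M,2,172,4,41,5136,125.3,24,2014-08-29,2014-10-08
18,DF,intratropical,M,1,88,2,25,2844,113.7,13,2014-07-18,2014-08-11
19,DF,intratropical,M,1,111,1,16,2604,162.8,8,2014-08-04,2014-08-19
20,DF,intratropical,M,1,114,3,20,3290,164.5,15,2014-07-22,2014-08-10
21,DF,intratropical,M,1,146,3,20,3259,162.9,10,2014-08-02,2014-08-21
22,EEI,intratropical,F,1,139,3,25,3037,121.5,16,2015-08-12,2015-09-05
23,EEI,intratropical,M,1,145,3,29,3757,129.6,10,2014-08-16,2014-09-13
24,EEI,intratropical,M,3,169,1,22,3587,163.1,8,2014-08-12,2014-09-02
25,EEI,intratropical,M,1,158,3,32,3818,119.3,15,2014-08-05,2014-09-05
26,EEI,intratropical,M,3,155,4,29,3523,121.5,24,2014-07-31,2014-08-28
27,EEI,intratropical,M,3,161,2,19,3628,190.9,9,2014-08-16,2014-09-03
28,EEI,intratropical,M,1,147,4,27,3555,131.7,17,2014-07-28,2014-08-23
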