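subject_id,group,session,age,sex,fd,ahrs,panss_pos,panss_neg,panss_gen,panss_total
SZ001,SZ,baseline,18.0,female,0.225,20.0,15.8,20.2,35.4,72.4
SZ001,SZ,post,18.0,female,0.225,10.0,17.3,10.5,45.2,81.2
SZ002,SZ,baseline,25.3,male,0.283,34.9,29.5,27.9,36.0,83.1
SZ002,SZ,post,25.3,male,0.283,9.2,22.3,19.1,39.4,77.7
SZ003,SZ,baseline,26.2,male,0.276,26.2,27.6,10.7,41.4,73.9
SZ003,SZ,post,26.2,male,0.276,18.0,19.4,24.7,43.4,69.4
SZ004,SZ,baseline,27.5,male,0.261,27.0,19.1,15.1,34.2,84.9
SZ004,SZ,post,27.5,male,0.261,25.0,13.2,19.3,57.9,66.1
SZ005,SZ,baseline,30.0,male,0.247,15.9,23.9,15.4,46.7,117.6
SZ005,SZ,post,30.0,male,0.247,14.6,19.3,16.0,48.8,77.8
SZ006,SZ,baseline,29.0,female,0.263,20.4,21.5,23.9,49.8,97.3
SZ006,SZ,post,29.0,female,0.263,18.0,17.9,10.2,43.1,98.7
SZ007,SZ,baseline,25.4,male,0.216,30.6,17.6,15.6,47.9,65.9
SZ007,SZ,post,25.4,male,0.216,11.3,18.1,17.0,48.4,74.1
SZ008,SZ,baseline,33.3,male,0.275,20.9,23.6,21.2,52.0,104.5
SZ008,SZ,post,33.3,male,0.275,11.6,16.1,12.4,49.5,100.9
SZ009,SZ,baseline,24.9,female,0.273,30.1,17.9,20.2,39.8,83.6
SZ009,SZ,post,24.9,female,0.273,9.3,24.0,17.5,47.5,76.1
SZ010,SZ,baseline,18.0,male,0.272,16.3,21.7,17.0,44.6,68.1
SZ010,SZ,post,18.0,male,0.272,5.8,14.1,23.7,63.2,79.2
SZ011,SZ,baseline,29.1,female,0.259,24.6,23.6,21.9,33.6,88.1
SZ011,SZ,post,29.1,female,0.259,14.9,22.5,25.6,52.1,85.7
SZ012,SZ,baseline,29.5,female,0.256,29.5,26.2,14.3,47.1,79.6
SZ012,SZ,post,29.5,female,0.256,8.5,16.2,10.3,35.7,76.4
SZ013,SZ,baseline,28.1,female,0.301,25.7,19.2,23.1,40.5,87.1
SZ013,SZ,post,28.1,female,0.301,10.4,16.3,23.6,46.7,90.4
SZ014,SZ,baseline,44.0,female,0.278,23.2,23.0,16.8,48.3,92.4
SZ014,SZ,post,44.0,female,0.278,9.0,17.8,16.6,43.3,57.6
SZ015,SZ,baseline,24.1,female,0.252,29.7,22.1,22.8,52.6,79.0
SZ015,SZ,post,24.1,female,0.252,12.6,20.2,27.3,47.1,73.5
SZ016,SZ,baseline,29.2,male,0.249,34.3,21.9,25.6,47.1,80.3
SZ016,SZ,post,29.2,male,0.249,10.2,20.1,26.0,39.1,78.2
SZ017,SZ,baseline,29.7,male,0.263,27.6,24.3,24.0,40.8,87.9
SZ017,SZ,post,29.7,male,0.263,10.4,19.7,9.7,51.0,87.7
SZ018,SZ,baseline,26.6,female,0.28,33.2,29.7,16.5,41.2,104.4
SZ018,SZ,post,26.6,female,0.28,11.9,22.7,22.8,40.4,96.3
SZ019,SZ,baseline,34.0,male,0.358,30.3,16.6,13.2,53.6,100.2
SZ019,SZ,post,34.0,male,0.358,11.5,20.3,16.3,57.6,85.7
SZ020,SZ,baseline,27.4,male,0.297,22.4,20.1,19.0,32.7,98.4
SZ020,SZ,post,27.4,male,0.297,9.8,15.5,8.9,39.0,63.6
SZ021,SZ,baseline,18.0,female,0.303,26.6,16.4,12.1,37.4,87.5
SZ021,SZ,post,18.0,female,0.303,6.7,24.1,17.7,46.2,69.5
SZ022,SZ,baseline,38.9,male,0.263,32.9,32.0,17.1,42.4,85.6
SZ022,SZ,post,38.9,male,0.263,11.9,18.0,12.5,43.7,88.8
SZ023,SZ,baseline,21.3,male,0.228,19.1,17.4,19.4,48.3,98.0
SZ023,SZ,post,21.3,male,0.228,4.9,20.6,26.1,50.0,73.0
SZ024,SZ,baseline,31.9,female,0.235,19.3,29.9,19.4,24.3,122.1
SZ024,SZ,post,31.9,female,0.235,17.8,18.5,17.7,47.0,68.0
SZ025,SZ,baseline,27.7,male,0.27,22.3,17.8,17.6,45.0,90.2
SZ025,SZ,post,27.7,male,0.27,15.1,23.8,24.9,53.5,80.6
SZ026,SZ,baseline,25.6,male,0.307,13.3,18.7,8.7,35.6,78.2
SZ026,SZ,post,25.6,male,0.307,10.7,15.6,16.7,32.2,64.0
SZ027,SZ,baseline,22.7,female,0.223,24.3,20.9,22.2,46.8,68.2
SZ027,SZ,post,22.7,female,0.223,10.2,17.5,17.6,52.1,81.2
SZ028,SZ,baseline,27.9,female,0.207,29.1,18.5,24.3,33.7,82.2
SZ028,SZ,post,27.9,female,0.207,16.1,24.9,17.7,65.0,76.1
SZ029,SZ,baseline,18.9,male,0.249,25.6,24.7,14.5,31.3,89.0
SZ029,SZ,post,18.9,male,0.249,8.0,19.2,19.4,38.2,84.0
SZ030,SZ,baseline,23.1,female,0.255,17.0,18.7,17.5,32.0,107.7
SZ030,SZ,post,23.1,female,0.255,10.5,18.9,19.8,29.4,80.1
SZ031,SZ,baseline,25.1,male,0.343,13.7,19.3,23.8,46.4,87.3
SZ031,SZ,post,25.1,male,0.343,3.6,22.0,26.6,45.6,70.7
SZ032,SZ,baseline,21.2,male,0.269,26.3,21.9,16.6,35.9,100.4
SZ032,SZ,post,21.2,male,0.269,7.0,17.8,20.2,53.5,94.4
SZ033,SZ,baseline,18.0,female,0.241,28.8,16.0,19.5,59.6,95.0
SZ033,SZ,post,18.0,female,0.241,9.8,22.4,6.5,53.7,62.0
SZ034,SZ,baseline,18.3,female,0.198,31.2,20.2,31.3,42.1,101.5
SZ034,SZ,post,18.3,female,0.198,28.4,17.5,17.1,52.0,76.0
SZ035,SZ,baseline,26.3,male,0.252,23.8,25.3,23.4,29.9,91.4
SZ035,SZ,post,26.3,male,0.252,11.1,18.7,20.0,48.3,83.1
SZ036,SZ,baseline,24.2,male,0.283,16.2,16.8,13.2,51.1,83.2
SZ036,SZ,post,24.2,male,0.283,6.5,19.5,24.3,54.8,72.7
SZ037,SZ,baseline,25.5,female,0.303,26.2,22.3,27.3,52.9,93.6
SZ037,SZ,post,25.5,female,0.303,11.0,16.6,29.3,37.2,78.0
SZ038,SZ,baseline,21.6,female,0.273,20.6,24.6,24.3,40.4,97.9
SZ038,SZ,post,21.6,female,0.273,7.2,14.5,17.8,54.7,89.7
SZ039,SZ,baseline,18.0,male,0.191,16.2,23.0,20.6,43.6,114.5
SZ039,SZ,post,18.0,male,0.191,5.9,17.2,21.1,43.7,60.8
SZ040,SZ,baseline,21.2,male,0.239,31.1,25.2,19.3,51.0,102.5
SZ040,SZ,post,21.2,male,0.239,21.4,18.7,24.0,54.0,78.9
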