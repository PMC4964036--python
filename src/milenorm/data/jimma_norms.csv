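item_code,p25_months,p50_months,p75_months,p90_months,flag
PS1,0.0,0.0,0.0,0.0,similar
PS2,0.8,1.1,1.3,1.6,similar
PS3,1.1,1.4,1.6,1.9,earlier
PS4,1.6,1.8,3.2,4.1,similar
PS5,3.1,4.5,6.0,7.6,later
PS6,4.0,5.9,8.2,10.5,later
PS7,6.9,8.1,9.4,10.6,similar
PS8,6.1,8.1,10.1,12.2,similar
PS9,8.2,10.0,11.8,13.6,similar
PS10,10.4,12.2,14.0,15.8,similar
PS11,9.7,11.6,13.4,15.2,similar
PS12,9.7,11.8,13.9,16.0,similar
PS13,12.9,15.9,18.4,20.9,later
PS14,11.7,14.5,17.2,20.0,similar
PS15,15.5,20.4,24.5,28.6,later
PS16,14.4,19.5,24.5,29.7,later
PS17,25.3,31.8,38.1,44.5,later
PS18,20.4,24.8,29.1,33.4,similar
PS19,22.9,27.4,32.4,37.4,similar
PS20,22.8,"28,3",33.4,38.6,similar
PS21,34.2,40.8,47.3,53.8,later
PS22,43.9,50.5,57.0,63.5,later
PS23,31.8,41.6,51.2,60.9,similar
PS24,37.9,46.8,55.5,64.4,similar
PS25,31.7,46.5,61.2,76.0,similar
PS26,60.1,70.4,80.6,90.8,similar
FM1,0.0,0.1,0.1,0.2,earlier
FM2,1.3,1.5,2.2,2.7,similar
FM3,2.4,3.0,3.6,4.1,similar
FM4,2.5,3.1,3.7,4.3,similar
FM5,3.1,3.7,4.3,4.9,similar
FM6,4.1,4.5,5.0,5.4,similar
FM7,4.2,4.7,5.2,5.6,similar
FM8,4.9,5.4,6.0,6.6,similar
FM9,5.3,5.9,6.4,6.9,similar
FM10,6.2,7.4,8.5,9.7,later
FM11,5.8,6.9,8.2,9.5,similar
FM12,6.5,7.5,8.7,9.9,similar
FM13,7.4,9.3,11.3,13.3,later
FM14,8.7,10.2,11.7,13.1,similar
FM15,10.7,13.4,16.0,18.6,later
FM16,10.9,13.5,16.0,18.5,similar
FM17,12.6,15.6,18.3,21.0,similar
FM18,16.4,19.3,22.2,25.1,similar
FM19,19.7,23.1,26.6,30.1,similar
FM20,25.9,32.4,37.7,43.0,later
FM21,22.1,29.4,35.0,40.6,similar
FM22,27.0,32.8,38.4,44.2,similar
FM23,38.7,43.1,47.3,51.6,similar
FM24,44.0,48.2,52.3,56.4,similar
FM25,33.8,40.4,46.9,53.4,similar
FM26,33.8,40.4,46.9,53.4,earlier
FM27,45.7,51.8,57.7,63.6,similar
FM28,52.4,57.5,62.4,67.4,similar
FM29,52.3,58.2,64.0,69.8,similar
LA1,0.0,0.0,0.0,0.0,similar
LA2,0.0,0.0,0.3,1.0,later
LA3,1.4,1.5,1.6,1.6,earlier
LA4,2.0,2.2,2.5,2.7,earlier
LA5,2.2,2.5,2.8,3.2,earlier
LA6,3.7,4.3,4.8,5.4,similar
LA7,4.5,5.2,5.8,6.5,similar
LA8,4.6,5.5,6.3,7.1,similar
LA9,5.2,6.5,7.8,9.1,similar
LA10,5.7,6.7,7.8,8.8,similar
LA11,6.2,7.5,8.8,10.1,similar
LA12,7.0,8.5,10.0,11.5,similar
LA13,8.8,10.2,11.6,12.9,similar
LA14,10.1,11.9,13.6,15.3,similar
LA15,11.5,13.8,15.9,18.0,similar
LA16,13.5,15.6,17.7,19.8,similar
LA17,"16,5",19.1,21.8,24.4,later
LA18,20.8,24.0,27.2,30.3,later
LA19,18.7,21.3,23.9,26.4,similar
LA20,20.1,23.2,26.2,29.3,similar
LA21,20.3,23.0,25.6,28.2,similar
LA22,25.9,31.0,35.9,40.9,later
LA23,20.5,24.2,27.8,31.5,earlier
LA24,27.6,32.5,37.3,42.1,later
LA25,24.5,29.5,34.4,39.4,similar
LA26,30.9,35.1,39.1,43.3,similar
LA27,40.3,45.1,49.8,54.6,later
LA28,30.4,35.6,40.7,45.8,similar
LA29,36.6,41.9,47.0,52.2,later
LA30,32.3,37.5,42.7,47.8,similar
LA31,32.4,38.5,44.4,50.4,similar
LA32,28.4,36.3,44.0,51.8,similar
LA33,30.8,37.5,44.0,50.7,earlier
LA34,51.9,56.8,61.5,66.3,later
LA35,47.4,54.3,61.0,67.8,similar
LA36,34.5,40.6,46.5,52.5,earlier
LA37,49.0,54.3,59.4,64.6,similar
LA38,48.5,54.0,59.2,64.5,similar
LA39,59.1,66.8,74.2,81.8,later
GM1,0.0,0.0,0.0,0.0,similar
GM2,0.0,0.1,0.4,0.7,later
GM3,1.6,2.0,2.3,2.6,similar
GM4,2.9,3.2,3.6,3.9,similar
GM5,3.0,3.3,3.6,3.9,similar
GM6,3.1,3.4,3.6,3.8,earlier
GM7,3.9,4.3,4.6,4.9,similar
GM8,3.8,4.4,4.9,5.4,similar
GM9,"4,4",4.9,5.5,6.0,similar
GM10,5.4,6.0,6.6,7.3,similar
GM11,6.5,7.3,8.3,9.3,similar
GM12,7.2,8.0,8.9,9.9,similar
GM13,7.4,8.3,9.2,10.1,similar
GM14,8.6,9.7,10.7,11.6,similar
GM15,9.8,11.3,12.3,13.4,similar
GM16,11.6,13.2,14.8,16.4,later
GM17,11.3,13.1,14.9,16.7,later
GM18,11.9,14.9,17.4,19.9,later
GM19,14.4,16.6,18.9,21.2,similar
GM20,13.9,16.9,19.6,22.3,similar
GM21,14.2,17.6,21.0,24.4,similar
GM22,24.0,27.0,31.0,35.0,later
GM23,16.9,22.1,27.2,32.4,similar
GM24,31.7,35.6,39.3,43.1,later
GM25,23.4,28.9,33.0,37.1,similar
GM26,23.9,31.2,36.4,41.6,earlier
GM27,31.9,38.5,45.0,51.5,similar
GM28,29.8,36.1,42.2,48.4,earlier
GM29,33.8,40.0,46.0,52.1,earlier
GM30,39.2,44.8,50.2,55.8,earlier
GM31,49.1,55.5,61.8,68.1,similar
GM32,41.8,47.9,53.8,59.7,earlier
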