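id,group,sex,birth_ga_weeks,pma_scan_weeks,postnatal_age_days,birth_weight_kg,head_circumference_cm
01,R+,male,40.57,43.86,23,3.37,37.9
02,R+,female,40.14,44.29,29,3.95,36.7
03,R+,male,35.43,42.86,52,3.06,33.0
04,R+,male,39.57,43.00,24,3.60,37.0
05,R+,female,40.57,44.86,30,4.70,38.0
06,R+,female,39.29,40.57,9,2.94,34.0
07,R+,male,35.57,40.00,31,2.82,38.0
08,R+,male,34.43,41.43,49,2.80,35.0
09,R+,male,39.14,44.00,34,3.50,36.5
10,R+,female,41.14,44.00,20,3.10,34.0
11,R+,male,39.00,41.14,15,2.84,35.0
12,R+,male,40.29,42.71,17,3.90,37.5
13,R+,male,38.86,43.29,31,3.43,38.0
14,R+,male,40.71,40.86,1,3.84,34.0
15,R+,male,40.00,42.00,14,3.69,34.5
16,R+,female,40.43,44.14,26,2.80,35.8
17,R+,male,39.00,42.00,21,4.10,38.0
18,R+,male,40.43,43.29,20,3.44,35.2
19,R-,male,40.71,43.29,18,3.20,37.4
20,R-,male,39.14,41.57,17,3.15,34.3
21,R-,male,40.14,43.86,26,3.92,37.5
22,R-,male,39.14,41.71,18,3.29,37.5
23,R-,male,40.14,43.14,21,3.80,35.0
24,R-,male,37.86,40.29,17,3.34,34.0
25,R-,male,37.43,39.29,13,3.06,35.0
26,R-,female,38.57,41.14,18,3.25,35.6
27,R-,male,41.00,43.00,14,3.10,37.0
28,R-,female,40.57,42.86,16,3.02,34.4
29,R-,male,40.14,41.43,9,3.11,35.1
30,R-,female,38.86,41.29,17,4.25,36.5
31,R-,male,41.14,43.57,17,4.04,38.0
32,R-,male,36.57,43.00,45,2.52,35.2
33,R-,female,38.71,42.14,24,3.01,35.0
34,R-,male,38.86,40.57,12,3.60,35.0
35,R-,male,42.00,44.57,18,3.78,36.0
36,R-,female,40.00,43.57,25,3.44,36.0
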