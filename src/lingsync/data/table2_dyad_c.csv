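dyad_id,role,session_index,analytic,clout,authentic,tone
C,client,1,8.31,20.79,83.95,30.48
C,client,2,9.76,17.3,84.89,39.14
C,client,3,12.23,34.34,77.4,37.81
C,client,4,5.99,12.05,89.67,33.92
C,client,5,7.8,23.77,84.25,52.62
C,client,6,6.86,15.47,84.35,28.09
C,client,7,10.71,14.55,84.31,42.98
C,client,8,13.8,16.09,89.81,56.77
C,client,9,7.4,19,80.6,33.32
C,client,10,8.4,20.27,76.16,27.55
C,client,11,12.11,12.48,84.71,64.38
C,client,12,9,13.76,89.37,35.98
C,client,13,8.1,32.02,73.69,31.32
C,client,14,10.38,10.52,96.12,36.5
C,client,15,9.93,24.98,89.52,34.03
C,client,16,16.14,22.22,85.27,40.3
C,client,17,13.69,38.62,65.02,28.35
C,client,18,8.72,21.52,84.27,34.38
C,client,19,9.96,25.35,90.8,61.12
C,client,20,10.09,11.12,92.02,41
C,therapist,1,9.33,84.32,53.22,45.87
C,therapist,2,10.82,71.38,50.59,41.91
C,therapist,3,14.26,60.8,59.47,34.18
C,therapist,4,3.63,46.31,68.51,46.11
C,therapist,5,4.78,68.84,55.12,30.38
C,therapist,6,5.17,69.12,70.92,35.67
C,therapist,7,8.82,50.61,76.79,42.31
C,therapist,8,20.29,67.18,66.65,50.7
C,therapist,9,5.65,47.84,78.43,43.22
C,therapist,10,9.7,73.77,66.41,37.37
C,therapist,11,2.54,43.82,85.18,51.45
C,therapist,12,7.23,45.65,84.16,30.59
C,therapist,13,8.09,62.79,72.3,28.49
C,therapist,14,6.27,37.4,86.97,15.06
C,therapist,15,20.86,70.2,51.28,28.22
C,therapist,16,10.81,56.49,67.51,61.87
C,therapist,17,7.25,63.79,75.51,16.18
C,therapist,18,8.91,70.43,71.29,50.49
C,therapist,19,3.91,91.21,60.97,64.83
C,therapist,20,12.18,46.21,75.23,40.69
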