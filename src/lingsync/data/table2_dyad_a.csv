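dyad_id,role,session_index,analytic,clout,authentic,tone
A,client,1,12.62,41.26,63.11,67.58
A,client,2,17.73,21.95,69.21,60.4
A,client,3,35.24,20.39,80.5,66.26
A,client,4,30.8,25.32,68.91,40.86
A,client,5,10.08,14.08,69.39,66.7
A,client,6,19.74,35.59,69.84,50.09
A,client,7,21.73,42.54,72.59,49.84
A,client,8,15.09,51.7,28.18,42.92
A,client,9,20.46,14.71,87.51,49.69
A,client,10,10.43,32.1,67.85,50.33
A,client,11,17.74,32.18,67.41,77.29
A,client,12,11.08,18.31,86.55,67.23
A,client,13,17.27,25.92,56.74,75.06
A,client,14,21.27,15.99,87.01,56.85
A,client,15,29.99,37.22,52.08,41.54
A,therapist,1,33.45,73.58,72.27,43.14
A,therapist,2,7.39,69.04,69,72.32
A,therapist,3,9.49,60.35,66.71,42.41
A,therapist,4,20.15,65.65,50.19,22.31
A,therapist,5,21.73,61.72,50.61,58.63
A,therapist,6,18.49,55.65,59.94,30.12
A,therapist,7,20.23,71.69,56.41,31.35
A,therapist,8,11.39,63.4,24.98,28.62
A,therapist,9,30.32,67.62,67.4,68.9
A,therapist,10,21.96,34.07,73.84,49.06
A,therapist,11,15.17,48.14,65,85.53
A,therapist,12,13.79,68.94,86.4,91.04
A,therapist,13,19.69,64.82,75.53,44.51
A,therapist,14,38.33,80.23,73.1,91.52
A,therapist,15,37.64,75.49,54.67,56.41
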