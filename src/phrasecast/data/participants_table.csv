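user,age_when_posting,age_at_stroke,time_since_stroke,sex,identity,times_metaphor_used,total_posts,superuser
A,54,46,8,F,Survivor,51,4932,Yes
B,67,55,12,M,Survivor,2,542,Yes
C,67,67,0,F,Survivor,1,178,Yes
D,55,55,0,M,Survivor,1,19,No
E,59,49,10,F,Caregiver,1,2,No
F,42,40,2,F,Survivor,3,291,Yes
G,50,47,3,M,Survivor,1,58,No
H,1,1,0,F,Caregiver,1,27,No
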