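item,nausea,oculomotor,disorientation
general_discomfort,1,1,0
fatigue,0,1,0
headache,0,1,0
eyestrain,0,1,0
difficulty_focusing,0,1,1
increased_salivation,1,0,0
sweating,1,0,0
nausea,1,0,1
difficulty_concentrating,1,1,0
fullness_of_head,0,0,1
blurred_vision,0,1,1
dizziness_eyes_open,0,0,1
dizziness_eyes_closed,0,0,1
vertigo,0,0,1
stomach_awareness,1,0,0
burping,1,0,0
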