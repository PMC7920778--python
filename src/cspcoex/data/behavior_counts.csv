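behavior,year,species,hit,miss,false_alarm,correct_rejection
male_mating_attempt,2014,H. yedoensis,30,115,13,22
male_mating_attempt,2014,H. axyridis,47,40,10,32
male_mating_attempt,2015,H. yedoensis,28,95,3,13
male_mating_attempt,2015,H. axyridis,67,26,8,15
female_rejection,2014,H. yedoensis,16,14,3,6
female_rejection,2014,H. axyridis,14,33,7,7
female_rejection,2015,H. yedoensis,13,18,8,13
female_rejection,2015,H. axyridis,97,57,3,0
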