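category,breed,phenotype,sex,marker,genotype,count,uncertain
completely_polled,Australian Poll Merino,unknown,male,OAR10_29511510.1,A/G,5,0
completely_polled,Australian Poll Merino,unknown,male,OAR10_29511510.1,G/G,93,0
completely_polled,Australian Suffolk,unknown,male,OAR10_29511510.1,A/G,1,0
completely_polled,Australian Suffolk,unknown,male,OAR10_29511510.1,G/G,108,0
completely_polled,Comisana,unknown,female,OAR10_29511510.1,A/G,5,0
completely_polled,Comisana,unknown,female,OAR10_29511510.1,G/G,93,0
completely_polled,East Friesian Brown,unknown,male,OAR10_29511510.1,G/G,15,0
completely_polled,East Friesian Brown,unknown,female,OAR10_29511510.1,A/G,1,0
completely_polled,East Friesian Brown,unknown,female,OAR10_29511510.1,G/G,23,0
completely_polled,Irish Suffolk,unknown,male,OAR10_29511510.1,A/G,1,0
completely_polled,Irish Suffolk,unknown,male,OAR10_29511510.1,G/G,38,0
completely_polled,Irish Suffolk,unknown,female,OAR10_29511510.1,G/G,16,0
completely_polled,Rasa Aragonesa,unknown,male,OAR10_29511510.1,A/G,1,0
completely_polled,Rasa Aragonesa,unknown,male,OAR10_29511510.1,G/G,3,0
completely_polled,Rasa Aragonesa,unknown,female,OAR10_29511510.1,A/G,1,0
completely_polled,Rasa Aragonesa,unknown,female,OAR10_29511510.1,G/G,17,0
completely_polled,Scottish Texel,unknown,male,OAR10_29511510.1,A/G,9,0
completely_polled,Scottish Texel,unknown,male,OAR10_29511510.1,G/G,31,0
completely_polled,Scottish Texel,unknown,female,OAR10_29511510.1,A/G,4,0
completely_polled,Scottish Texel,unknown,female,OAR10_29511510.1,G/G,36,0
sex_dependent,Ethiopian Menz,unknown,male,OAR10_29511510.1,A/G,1,0
sex_dependent,Ethiopian Menz,unknown,male,OAR10_29511510.1,G/G,17,0
sex_dependent,Ethiopian Menz,unknown,female,OAR10_29511510.1,A/G,3,0
sex_dependent,Ethiopian Menz,unknown,female,OAR10_29511510.1,G/G,13,0
sex_dependent,Bangladeshi Garole,unknown,male,OAR10_29511510.1,G/G,6,0
sex_dependent,Bangladeshi Garole,unknown,female,OAR10_29511510.1,G/G,18,0
sex_dependent,Garut,unknown,male,OAR10_29511510.1,G/G,8,0
sex_dependent,Garut,unknown,female,OAR10_29511510.1,G/G,14,0
sex_dependent,Indian Garole,unknown,male,OAR10_29511510.1,G/G,4,0
sex_dependent,Indian Garole,unknown,female,OAR10_29511510.1,G/G,22,0
sex_dependent,Rambouillet,unknown,male,OAR10_29511510.1,A/G,1,0
sex_dependent,Rambouillet,unknown,male,OAR10_29511510.1,G/G,75,0
sex_dependent,Rambouillet,unknown,female,OAR10_29511510.1,G/G,26,0
completely_horned,Dorset Horn,unknown,male,OAR10_29511510.1,A/A,3,0
completely_horned,Dorset Horn,unknown,male,OAR10_29511510.1,A/G,1,0
completely_horned,Dorset Horn,unknown,female,OAR10_29511510.1,A/A,12,0
completely_horned,Dorset Horn,unknown,female,OAR10_29511510.1,A/G,5,0
completely_horned,Tibetan,unknown,male,OAR10_29511510.1,A/A,19,0
completely_horned,Tibetan,unknown,male,OAR10_29511510.1,A/G,3,0
completely_horned,Tibetan,unknown,female,OAR10_29511510.1,A/A,14,0
completely_horned,Tibetan,unknown,female,OAR10_29511510.1,A/G,1,0
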