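category,breed,phenotype,sex,marker,genotype,count,uncertain
unknown,East Friesian (White) x Grey Horned Heidschnucke,horned,male,ins1780,anc/der,3,0
unknown,East Friesian (White) x Grey Horned Heidschnucke,polled,female,ins1780,anc/der,3,0
unknown,Merinolandschaf x Grey Horned Heidschnucke,horned,male,ins1780,anc/der,2,0
unknown,Multi cross polled x horned,horned,female,ins1780,anc/anc,3,0
unknown,Multi cross polled x horned,polled,female,ins1780,anc/der,4,0
unknown,Multi cross polled x horned,polled,female,ins1780,der/der,2,0
unknown,Multi cross polled x horned,rudiments,female,ins1780,anc/der,1,0
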