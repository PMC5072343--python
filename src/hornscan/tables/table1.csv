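category,breed,phenotype,sex,marker,genotype,count,uncertain
completely_polled,Barbados Black Belly,polled,female,ins1780,anc/der,3,0
completely_polled,Barbados Black Belly,polled,unknown,ins1780,der/der,7,0
completely_polled,Bentheimer,polled,unknown,ins1780,der/der,4,0
completely_polled,Charollais,polled,unknown,ins1780,der/der,3,0
completely_polled,Coburger,polled,unknown,ins1780,der/der,18,0
completely_polled,East Friesian (White),polled,unknown,ins1780,der/der,20,0
completely_polled,German Blackheaded Mutton,polled,unknown,ins1780,der/der,20,0
completely_polled,German Brown Mountain,polled,unknown,ins1780,der/der,4,0
completely_polled,German White Mountain,polled,unknown,ins1780,der/der,20,0
completely_polled,Ile de France,polled,unknown,ins1780,der/der,3,0
completely_polled,Merinolandschaf,polled,unknown,ins1780,der/der,20,0
completely_polled,Pomeranian Coarsewool,polled,female,ins1780,anc/der,1,0
completely_polled,Pomeranian Coarsewool,polled,unknown,ins1780,der/der,18,0
completely_polled,Rhoen,polled,unknown,ins1780,der/der,20,0
completely_polled,Rouge du Roussillon,polled,unknown,ins1780,der/der,4,0
completely_polled,Shropshire,polled,unknown,ins1780,der/der,4,0
completely_polled,Suffolk,polled,unknown,ins1780,der/der,17,0
completely_polled,Texel,polled,unknown,ins1780,der/der,20,0
completely_polled,White Polled Heidschnucke,polled,unknown,ins1780,der/der,2,0
completely_horned,Grey Horned Heidschnucke,horned,unknown,ins1780,anc/anc,26,0
completely_horned,Racka,horned,unknown,ins1780,anc/anc,7,0
completely_horned,Roux du Valais,horned,unknown,ins1780,anc/anc,2,0
completely_horned,Scottish Blackface,horned,unknown,ins1780,anc/anc,18,0
completely_horned,Soay,horned,unknown,ins1780,anc/anc,9,0
completely_horned,Valais Blacknose,horned,unknown,ins1780,anc/anc,18,0
completely_horned,White Horned Heidschnucke,horned,unknown,ins1780,anc/anc,2,0
completely_horned,Wiltshire Horn,horned,unknown,ins1780,anc/anc,2,0
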