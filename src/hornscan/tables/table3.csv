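category,breed,phenotype,sex,marker,genotype,count,uncertain
variable,Bavarian Forest,horned,male,ins1780,anc/anc,6,1
variable,Bavarian Forest,horned,male,ins1780,anc/der,3,1
variable,Bavarian Forest,horned,female,ins1780,anc/anc,1,1
variable,Bavarian Forest,horned,female,ins1780,anc/der,2,1
variable,Bavarian Forest,rudiments,female,ins1780,anc/der,1,1
variable,Bavarian Forest,polled,male,ins1780,anc/der,1,1
variable,Bavarian Forest,polled,female,ins1780,anc/der,3,1
variable,Bavarian Forest,polled,female,ins1780,der/der,1,1
variable,Bavarian Forest,scurred,male,ins1780,anc/der,2,1
variable,Bavarian Forest,scurred,female,ins1780,anc/der,3,1
variable,Alpines Steinschaf,horned,male,ins1780,anc/anc,6,1
variable,Alpines Steinschaf,horned,female,ins1780,anc/anc,6,1
variable,Alpines Steinschaf,rudiments,male,ins1780,anc/der,2,1
variable,Alpines Steinschaf,polled,male,ins1780,anc/der,1,1
variable,Alpines Steinschaf,polled,female,ins1780,anc/der,7,1
variable,Alpines Steinschaf,polled,female,ins1780,der/der,1,1
variable,Alpines Steinschaf,scurred,male,ins1780,der/der,1,0
variable,Walachenschaf,horned,male,ins1780,anc/anc,4,1
variable,Walachenschaf,horned,male,ins1780,anc/der,1,1
variable,Walachenschaf,horned,female,ins1780,anc/anc,5,1
variable,Walachenschaf,rudiments,female,ins1780,anc/anc,2,1
variable,Walachenschaf,rudiments,female,ins1780,anc/der,1,1
sex_dependent,Cres,polled,female,ins1780,anc/anc,1,0
sex_dependent,Cres,polled,female,ins1780,anc/der,1,1
sex_dependent,Krk,polled,female,ins1780,anc/der,3,1
variable,Travnicka Pramenka,horned,male,ins1780,anc/anc,2,1
variable,Travnicka Pramenka,horned,female,ins1780,anc/anc,12,1
variable,Travnicka Pramenka,rudiments,female,ins1780,anc/anc,6,1
variable,Travnicka Pramenka,rudiments,female,ins1780,anc/der,1,1
variable,Travnicka Pramenka,polled,male,ins1780,anc/der,4,1
variable,Travnicka Pramenka,polled,male,ins1780,der/der,1,1
variable,Travnicka Pramenka,polled,female,ins1780,anc/anc,13,0
variable,Travnicka Pramenka,polled,female,ins1780,anc/der,2,1
variable,Travnicka Pramenka,scurred,female,ins1780,anc/der,2,1
variable,Bovec-like (Krainer Steinschaf),horned,male,ins1780,der/der,5,0
variable,Bovec-like (Krainer Steinschaf),horned,female,ins1780,der/der,5,0
variable,Bovec-like (Krainer Steinschaf),rudiments,male,ins1780,der/der,1,0
variable,Bovec-like (Krainer Steinschaf),polled,male,ins1780,der/der,3,0
variable,Bovec-like (Krainer Steinschaf),polled,female,ins1780,der/der,8,0
variable,Bovec-like (Krainer Steinschaf),scurred,female,ins1780,der/der,1,0
variable,Dorper,horned,male,ins1780,der/der,8,0
variable,Dorper,polled,male,ins1780,der/der,6,0
variable,Dorper,scurred,male,ins1780,der/der,3,0
variable,Dorper,scurred,female,ins1780,der/der,7,0
sex_dependent,Cameroon,horned,male,ins1780,anc/anc,9,0
sex_dependent,Cameroon,horned,male,ins1780,anc/der,1,1
sex_dependent,Cameroon,polled,male,ins1780,anc/der,1,0
sex_dependent,Cameroon,polled,female,ins1780,anc/anc,11,0
sex_dependent,Cameroon,polled,female,ins1780,anc/der,2,1
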