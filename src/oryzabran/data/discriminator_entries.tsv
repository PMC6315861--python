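metabolite_id	cultivar_id	direction
quinate	DM-16	low
serotonin	DM-16	high
serotonin	Njavara	low
tryptophan	Rang Jey	low
tyrosine	Rang Jey	low
lysine	Chennula	low
n6,n6,n6-trimethyllysine	Chennula	low
threonine	Chennula	low
arginine	Chennula	low
n-methylproline	Gambiaka	high
stachydrine	Gambiaka	high
trans-4-hydroxyproline	Gambiaka	high
asparagine	Njavara	low
glutamate	Njavara	low
glutamine	Njavara	low
pyroglutamine	Njavara	low
taurine	Njavara	low
n-acetylglutamate	Njavara	high
pipecolate	Sawa Mahsuli	high
glycine	Sawa Mahsuli	high
methionine sulfoxide	Khao Gaew	low
aspartate	IAC 600	low
arabonate/xylonate	Khao Gaew	low
ribonate	Khao Gaew	low
glucosaminate	Njavara	low
aconitate	Njavara	low
α-ketoglutarate	Njavara	low
malate	IAC 600	low
malate	Calrose	high
erythritol	Basmati 217	high
γ-tocopherol/β-tocopherol	Sawa Mahsuli	low
γ-tocotrienol	Sawa Mahsuli	low
linoleate	RBT 300	low
linolenate	RBT 300	low
myristate	RBT 300	low
myristoleate	RBT 300	low
palmitate	RBT 300	low
palmitoleate	RBT 300	low
diacylglycerol (14:0/18:1, 16:0/16:1)	RBT 300	low
linoleoyl-linolenoyl-glycerol (18:2/18:3) [1]	RBT 300	low
linoleoyl-linolenoyl-glycerol (18:2/18:3) [2]	RBT 300	low
linoleoyl-linoleoyl-glycerol (18:2/18:2)	RBT 300	low
oleoyl-linoleoyl-glycerol (18:1/18:2) [1]	RBT 300	low
oleoyl-oleoyl-glycerol (18:1/18:1)	RBT 300	low
palmitoleoyl-linoleoyl-glycerol (16:1/18:2)	RBT 300	low
palmitoyl-palmitoyl-glycerol (16:0/16:0) [1]	RBT 300	low
1-linoleoylglycerol (18:2)	RBT 300	low
1-oleoylglycerol (18:1)	RBT 300	low
1-palmitoylglycerol (16:0)	RBT 300	low
12,13-dihome	RBT 300	low
9,10-dihome	RBT 300	low
9,10-epoxystearate	RBT 300	low
oleoyl-linoleoyl-glycerol (18:1/18:2) [2]	Rang Jey	low
oleoyl-oleoyl-glycerol (18:1/18:1)	Rang Jey	low
1-linoleoyl-gpe (18:2)	Rang Jey	low
1-palmitoyl-gpc (16:0)	Rang Jey	low
1-palmitoyl-gpe (16:0)	Rang Jey	low
palmitoyl-linoleoyl-glycerol (16:0/18:2) [1]	Jasmine 85	low
palmitoyl-linoleoyl-glycerol (16:0/18:2) [2]	Jasmine 85	low
palmitoyl-oleoyl-glycerol (16:0/18:1)	Jasmine 85	low
palmitoyl-palmitoyl-glycerol (16:0/16:0) [2]	Jasmine 85	low
glycerophosphoglycerol	Njavara	low
glycerophosphorylcholine (gpc)	Njavara	low
oleoyl-linoleoyl-glycerol (18:1/18:2) [3]	Chennula	low
2-oleoylglycerol (18:1)	Chennula	low
laurate	Chennula	high
guanine	Rang Jey	high
hypoxanthine	Rang Jey	high
adenosine	Rang Jey	low
1-methyladenine	RBT 300	high
adenosine 5'-monophosphate (amp)	RBT 300	high
adenine	Khao Gaew	low
4-hydroxybenzoate	Rang Jey	high
salicylate	Khao Gaew	low
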