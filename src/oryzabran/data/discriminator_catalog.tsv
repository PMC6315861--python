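metabolite_id	chemical_class	pathway
quinate	amino acids	aromatic amino acids (PEP-derived)
serotonin	amino acids	aromatic amino acids (PEP-derived)
tryptophan	amino acids	aromatic amino acids (PEP-derived)
tyrosine	amino acids	aromatic amino acids (PEP-derived)
asparagine	amino acids	aspartate family (OAA-derived)
aspartate	amino acids	aspartate family (OAA-derived)
lysine	amino acids	aspartate family (OAA-derived)
methionine sulfoxide	amino acids	aspartate family (OAA-derived)
n6,n6,n6-trimethyllysine	amino acids	aspartate family (OAA-derived)
pipecolate	amino acids	aspartate family (OAA-derived)
threonine	amino acids	aspartate family (OAA-derived)
arginine	amino acids	glutamate family (α-ketoglutarate-derived)
glutamate	amino acids	glutamate family (α-ketoglutarate-derived)
glutamine	amino acids	glutamate family (α-ketoglutarate-derived)
n-acetylglutamate	amino acids	glutamate family (α-ketoglutarate-derived)
n-methylproline	amino acids	glutamate family (α-ketoglutarate-derived)
pyroglutamine	amino acids	glutamate family (α-ketoglutarate-derived)
stachydrine	amino acids	glutamate family (α-ketoglutarate-derived)
trans-4-hydroxyproline	amino acids	glutamate family (α-ketoglutarate-derived)
glycine	amino acids	serine family (phosphoglycerate-derived)
taurine	amino acids	serine family (phosphoglycerate-derived)
arabonate/xylonate	carbohydrates	amino sugar and nucleotide sugar metabolism
erythritol	carbohydrates	amino sugar and nucleotide sugar metabolism
glucosaminate	carbohydrates	amino sugar and nucleotide sugar metabolism
ribonate	carbohydrates	amino sugar and nucleotide sugar metabolism
aconitate	carbohydrates	TCA cycle
α-ketoglutarate	carbohydrates	TCA cycle
malate	carbohydrates	TCA cycle
γ-tocopherol/β-tocopherol	cofactors & vitamins	tocopherol metabolism
γ-tocotrienol	cofactors & vitamins	tocopherol metabolism
laurate	lipids	free fatty acid
linoleate	lipids	free fatty acid
linolenate	lipids	free fatty acid
myristate	lipids	free fatty acid
myristoleate	lipids	free fatty acid
palmitate	lipids	free fatty acid
palmitoleate	lipids	free fatty acid
diacylglycerol (14:0/18:1, 16:0/16:1)	lipids	glycerolipids (diacyl)
linoleoyl-linolenoyl-glycerol (18:2/18:3) [1]	lipids	glycerolipids (diacyl)
linoleoyl-linolenoyl-glycerol (18:2/18:3) [2]	lipids	glycerolipids (diacyl)
linoleoyl-linoleoyl-glycerol (18:2/18:2)	lipids	glycerolipids (diacyl)
oleoyl-linoleoyl-glycerol (18:1/18:2) [1]	lipids	glycerolipids (diacyl)
oleoyl-linoleoyl-glycerol (18:1/18:2) [2]	lipids	glycerolipids (diacyl)
oleoyl-linoleoyl-glycerol (18:1/18:2) [3]	lipids	glycerolipids (diacyl)
oleoyl-oleoyl-glycerol (18:1/18:1)	lipids	glycerolipids (diacyl)
palmitoleoyl-linoleoyl-glycerol (16:1/18:2)	lipids	glycerolipids (diacyl)
palmitoyl-linoleoyl-glycerol (16:0/18:2) [1]	lipids	glycerolipids (diacyl)
palmitoyl-linoleoyl-glycerol (16:0/18:2) [2]	lipids	glycerolipids (diacyl)
palmitoyl-oleoyl-glycerol (16:0/18:1)	lipids	glycerolipids (diacyl)
palmitoyl-palmitoyl-glycerol (16:0/16:0) [1]	lipids	glycerolipids (diacyl)
palmitoyl-palmitoyl-glycerol (16:0/16:0) [2]	lipids	glycerolipids (diacyl)
1-linoleoylglycerol (18:2)	lipids	glycerolipids (monoacyl)
1-oleoylglycerol (18:1)	lipids	glycerolipids (monoacyl)
1-palmitoylglycerol (16:0)	lipids	glycerolipids (monoacyl)
2-oleoylglycerol (18:1)	lipids	glycerolipids (monoacyl)
1-linoleoyl-gpe (18:2)	lipids	lyso-phospholipids
1-palmitoyl-gpc (16:0)	lipids	lyso-phospholipids
1-palmitoyl-gpe (16:0)	lipids	lyso-phospholipids
12,13-dihome	lipids	oxylipins
9,10-dihome	lipids	oxylipins
9,10-epoxystearate	lipids	oxylipins
glycerophosphoglycerol	lipids	phospholipid metabolism
glycerophosphorylcholine (gpc)	lipids	phospholipid metabolism
1-methyladenine	nucleotides	purine metabolism
adenine	nucleotides	purine metabolism
adenosine	nucleotides	purine metabolism
adenosine 5'-monophosphate (amp)	nucleotides	purine metabolism
guanine	nucleotides	purine metabolism
hypoxanthine	nucleotides	purine metabolism
4-hydroxybenzoate	secondary metabolites	benzenoids
salicylate	secondary metabolites	benzenoids
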