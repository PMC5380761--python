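species	clade	subclades
PHYPA	outgroup
SELML	outgroup
PHODC	monocot
MUSAC	monocot
ORYSJ	monocot	Poaceae
ORYSI	monocot	Poaceae
BRADI	monocot	Poaceae
SETIT	monocot	Poaceae
MAIZE	monocot	Poaceae
SORBI	monocot	Poaceae
SOLTU	dicot	Solanaceae
SOLLC	dicot	Solanaceae
VITVI	dicot
LOTJA	dicot	Fabaceae
MEDTR	dicot	Fabaceae
GLYMA	dicot	Fabaceae
CAJCA	dicot	Fabaceae
PRUPE	dicot	Rosaceae
MALDO	dicot	Rosaceae
RICCO	dicot
JATCU	dicot
MANES	dicot
POPTR	dicot
CUCSA	dicot
CUCME	dicot
CARPA	dicot	Brassicales
ARATH	dicot	Brassicales,Brassicaceae
ARALY	dicot	Brassicales,Brassicaceae
BRARA	dicot	Brassicales,Brassicaceae
EUTSA	dicot	Brassicales,Brassicaceae
SCHPA	dicot	Brassicales,Brassicaceae
GOSRA	dicot
THECC	dicot
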