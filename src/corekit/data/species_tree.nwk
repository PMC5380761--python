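(PHYPA:1,(SELML:1,((PHODC:1,(MUSAC:1,((ORYSJ:1,ORYSI:1):1,(BRADI:1,(SETIT:1,(MAIZE:1,SORBI:1):1):1):1):1):1):1,((SOLTU:1,SOLLC:1):1,(VITVI:1,((((LOTJA:1,(MEDTR:1,(GLYMA:1,CAJCA:1):1):1):1,(PRUPE:1,MALDO:1):1):1,(((RICCO:1,(JATCU:1,MANES:1):1):1,POPTR:1):1,(CUCSA:1,CUCME:1):1):1):1,((CARPA:1,((ARATH:1,ARALY:1):1,(BRARA:1,(EUTSA:1,SCHPA:1):1):1):1):1,(GOSRA:1,THECC:1):1):1):1):1):1):1):1);
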