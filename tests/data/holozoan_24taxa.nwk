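(((((SALS5,MONBR)Choanoflagellata,(AMPQE,(TRIAD,((NEMVE,HYDMA)Cnidaria,(((CAEEL,(DROME,IXOSC)Arthropoda)Ecdysozoa,(HELRO,LOTGI)Lophotrochozoa)Protostomia,((STRPU,SACKO)Ambulacraria,(BRAFL,(CIOIN,(PETMA,(TETNI,(XENTR,(HUMAN,(ANOCA,CHICK)Sauria)Amniota)Tetrapoda)Euteleostomi)Vertebrata)Olfactores)Chordata)Deuterostomia)Bilateria)Planulozoa)ParaHoxozoa)Metazoa)Holozoa,NEUCR)Opisthokonta,DICDI)Amorphea,ARATH)Root;
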