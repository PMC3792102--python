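# rotamer library: ROT <res3> <n_atoms> <probability>; atom lines: name x y z q
ROT ALA 1 0.500000
SC1 0.550000 0.400000 1.500000 0.000000
ROT ALA 1 0.500000
SC1 0.550000 0.400000 -1.500000 0.000000
ROT ARG 3 0.500000
SC1 0.156218 0.604516 1.710000 0.000000
SC2 0.256218 0.904516 3.192000 0.000000
SC3 0.356218 1.204516 4.674000 0.400000
ROT ARG 3 0.500000
SC1 0.156218 0.604516 -1.710000 0.000000
SC2 0.256218 0.904516 -3.192000 0.000000
SC3 0.356218 1.204516 -4.674000 0.400000
ROT ASN 2 0.500000
SC1 0.374821 0.638541 1.665000 0.000000
SC2 0.474821 0.938541 3.108000 -0.120000
ROT ASN 2 0.500000
SC1 0.374821 0.638541 -1.665000 0.000000
SC2 0.474821 0.938541 -3.108000 -0.120000
ROT ASP 2 0.500000
SC1 0.321856 0.150957 1.530000 0.000000
SC2 0.421856 0.450957 2.856000 -0.450000
ROT ASP 2 0.500000
SC1 0.321856 0.150957 -1.530000 0.000000
SC2 0.421856 0.450957 -2.856000 -0.450000
ROT CYS 1 0.500000
SC1 0.115658 0.568873 1.515000 0.050000
ROT CYS 1 0.500000
SC1 0.115658 0.568873 -1.515000 0.050000
ROT GLN 2 0.500000
SC1 0.544169 0.346320 1.695000 0.000000
SC2 0.644169 0.646320 3.164000 -0.120000
ROT GLN 2 0.500000
SC1 0.544169 0.346320 -1.695000 0.000000
SC2 0.644169 0.646320 -3.164000 -0.120000
ROT GLU 2 0.500000
SC1 0.452110 0.598400 1.545000 0.000000
SC2 0.552110 0.898400 2.884000 -0.400000
ROT GLU 2 0.500000
SC1 0.452110 0.598400 -1.545000 0.000000
SC2 0.552110 0.898400 -2.884000 -0.400000
ROT GLY 0 0.500000
ROT GLY 0 0.500000
ROT HIS 2 0.500000
SC1 0.235099 0.641429 1.590000 0.000000
SC2 0.335099 0.941429 2.968000 0.150000
ROT HIS 2 0.500000
SC1 0.235099 0.641429 -1.590000 0.000000
SC2 0.335099 0.941429 -2.968000 0.150000
ROT ILE 2 0.500000
SC1 0.184773 0.178138 1.605000 0.000000
SC2 0.284773 0.478138 2.996000 0.000000
ROT ILE 2 0.500000
SC1 0.184773 0.178138 -1.605000 0.000000
SC2 0.284773 0.478138 -2.996000 0.000000
ROT LEU 2 0.500000
SC1 0.068914 0.495389 1.635000 0.000000
SC2 0.168914 0.795389 3.052000 0.000000
ROT LEU 2 0.500000
SC1 0.068914 0.495389 -1.635000 0.000000
SC2 0.168914 0.795389 -3.052000 0.000000
ROT LYS 3 0.500000
SC1 0.534830 0.485760 1.620000 0.000000
SC2 0.634830 0.785760 3.024000 0.000000
SC3 0.734830 1.085760 4.428000 0.450000
ROT LYS 3 0.500000
SC1 0.534830 0.485760 -1.620000 0.000000
SC2 0.634830 0.785760 -3.024000 0.000000
SC3 0.734830 1.085760 -4.428000 0.450000
ROT MET 2 0.500000
SC1 0.405961 0.173566 1.650000 0.000000
SC2 0.505961 0.473566 3.080000 0.050000
ROT MET 2 0.500000
SC1 0.405961 0.173566 -1.650000 0.000000
SC2 0.505961 0.473566 -3.080000 0.050000
ROT PHE 3 0.500000
SC1 0.053822 0.356455 1.560000 0.000000
SC2 0.153822 0.656455 2.912000 0.000000
SC3 0.253822 0.956455 4.264000 -0.030000
ROT PHE 3 0.500000
SC1 0.053822 0.356455 -1.560000 0.000000
SC2 0.153822 0.656455 -2.912000 0.000000
SC3 0.253822 0.956455 -4.264000 -0.030000
ROT PRO 1 0.500000
SC1 0.083697 0.274648 1.680000 0.000000
ROT PRO 1 0.500000
SC1 0.083697 0.274648 -1.680000 0.000000
ROT SER 1 0.500000
SC1 0.267872 0.152073 1.725000 -0.100000
ROT SER 1 0.500000
SC1 0.267872 0.152073 -1.725000 -0.100000
ROT THR 1 0.500000
SC1 0.491162 0.561112 1.740000 -0.100000
ROT THR 1 0.500000
SC1 0.491162 0.561112 -1.740000 -0.100000
ROT TRP 3 0.500000
SC1 0.477207 0.223655 1.770000 0.000000
SC2 0.577207 0.523655 3.304000 0.000000
SC3 0.677207 0.823655 4.838000 -0.050000
ROT TRP 3 0.500000
SC1 0.477207 0.223655 -1.770000 0.000000
SC2 0.577207 0.523655 -3.304000 0.000000
SC3 0.677207 0.823655 -4.838000 -0.050000
ROT TYR 3 0.500000
SC1 0.288452 0.649733 1.785000 0.000000
SC2 0.388452 0.949733 3.332000 0.000000
SC3 0.488452 1.249733 4.879000 -0.080000
ROT TYR 3 0.500000
SC1 0.288452 0.649733 -1.785000 0.000000
SC2 0.388452 0.949733 -3.332000 0.000000
SC3 0.488452 1.249733 -4.879000 -0.080000
ROT VAL 1 0.500000
SC1 0.050213 0.410329 1.755000 0.000000
ROT VAL 1 0.500000
SC1 0.050213 0.410329 -1.755000 0.000000
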