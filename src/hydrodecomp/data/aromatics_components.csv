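name,dA_hyd,e_reorg,dA_es,dA_disp,dA_cav,exp,asa
Benzene,-1.14,0.35,-1.14,-9.66,9.32,,
Toluene,-0.72,0.46,-1.45,-9.69,9.95,,
Biphenyl,-2.29,0.56,-2.22,-15.94,15.31,,
Naphthalene,-2.65,0.52,-2.72,-13.56,13.10,,
Fluorene,-3.01,0.78,-2.05,-16.87,15.13,,
Phenanthrene,-4.43,0.78,-3.33,-17.63,15.76,,
Pyrene,-4.67,0.82,-3.02,-19.70,17.23,,
Anthracene,-3.65,0.70,-3.36,-15.80,14.81,,
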