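site,from_aa,to_aa,energy,engine
124,GLY,ALA,-1.54,ds-cme
124,GLY,ARG,-2.59,ds-cme
124,GLY,ASN,-3.12,ds-cme
124,GLY,ASP,-1.24,ds-cme
124,GLY,CYS,-2.49,ds-cme
124,GLY,GLN,-2.05,ds-cme
124,GLY,GLU,-2.67,ds-cme
124,GLY,GLY,0,ds-cme
124,GLY,HIS,-2.67,ds-cme
124,GLY,ILE,-2.36,ds-cme
124,GLY,LEU,-3.74,ds-cme
124,GLY,LYS,-0.21,ds-cme
124,GLY,MET,-2.26,ds-cme
124,GLY,PHE,-3.14,ds-cme
124,GLY,PRO,5.28,ds-cme
124,GLY,SER,-1.51,ds-cme
124,GLY,THR,-1.74,ds-cme
124,GLY,TRP,-3.82,ds-cme
124,GLY,TYR,-3.03,ds-cme
137,GLY,ALA,-1.01,ds-cme
137,GLY,ARG,-1.28,ds-cme
137,GLY,ASN,-1.46,ds-cme
137,GLY,ASP,-0.72,ds-cme
137,GLY,CYS,-2.12,ds-cme
137,GLY,GLN,-0.8,ds-cme
137,GLY,GLU,-1.24,ds-cme
137,GLY,GLY,0,ds-cme
137,GLY,HIS,-1.05,ds-cme
137,GLY,ILE,-2.25,ds-cme
137,GLY,LEU,-2.15,ds-cme
137,GLY,LYS,-1.21,ds-cme
137,GLY,MET,-2.07,ds-cme
137,GLY,PHE,-2.83,ds-cme
137,GLY,PRO,-1.66,ds-cme
137,GLY,SER,-1.32,ds-cme
137,GLY,THR,-1.75,ds-cme
137,GLY,TRP,-3.58,ds-cme
137,GLY,TYR,-2.84,ds-cme
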