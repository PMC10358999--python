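site,from_aa,to_aa,energy,engine
217,HIS,ALA,-2.52,ds-cme
191,HIS,ALA,-2.06,ds-cme
195,HIS,ALA,-2.01,ds-cme
124,GLY,ALA,-1.54,ds-cme
216,HIS,ALA,-1.33,ds-cme
137,GLY,ALA,-1.01,ds-cme
20,ASP,ALA,-0.84,ds-cme
38,HIS,ALA,-0.84,ds-cme
205,GLY,ALA,-0.81,ds-cme
102,GLY,ALA,-0.62,ds-cme
135,GLY,ALA,-0.56,ds-cme
240,GLY,ALA,-0.56,ds-cme
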