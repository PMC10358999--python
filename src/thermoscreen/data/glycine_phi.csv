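residue,phi
29,77.5
49,-126.8
53,-119.7
102,-87.6
105,98.5
106,-57.8
108,-36.9
113,83.8
118,109
124,-78.8
125,77.2
135,-83.7
137,-66.4
144,81.2
146,-84.4
177,81.7
184,75.1
187,57.2
199,44.1
200,49.9
205,-73.3
240,-87.4
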