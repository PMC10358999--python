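mutation,energy,engine
G124W/G137W,-7.42,ds-cme
G124L/G137W,-7.26,ds-cme
G124L/G137Y,-6.76,ds-cme
G124W/G137F,-6.71,ds-cme
G124W/G137Y,-6.7,ds-cme
G124N/G137W,-6.67,ds-cme
G124L/G137I,-6.65,ds-cme
G124Y/G137W,-6.54,ds-cme
G124F/G137F,-6.47,ds-cme
G124L/G137F,-6.46,ds-cme
G124F/G137W,-6.39,ds-cme
G124H/G137W,-6.34,ds-cme
G124W/G137I,-6.24,ds-cme
G124F/G137Y,-6.21,ds-cme
G124L/G137Q,-6.16,ds-cme
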