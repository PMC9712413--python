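# Approximate neighbor corrections (ppm) added to a residue whose
# prev/next neighbor has the given type, schema v1.
# Columns: neighbor,position,nucleus,delta.
neighbor,position,nucleus,delta
P,next,CA,-1.9
P,next,H,0.1
P,next,N,0.9
G,next,N,-0.5
G,prev,N,-0.6
G,prev,H,-0.05
G,next,H,-0.05
G,prev,CA,0.1
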