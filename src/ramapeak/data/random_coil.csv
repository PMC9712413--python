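# Approximate random-coil chemical shifts (ppm), schema v1.
# Columns: residue,nucleus,shift.  Values are consensus textbook
# random-coil shifts, NOT a published neighbor-corrected data set;
# substitute your preferred table via RandomCoilTable.from_csv.
residue,nucleus,shift
A,H,8.24
A,N,123.8
A,CA,52.5
A,CB,19.1
C,H,8.32
C,N,118.8
C,CA,58.2
C,CB,28.0
D,H,8.34
D,N,120.4
D,CA,54.2
D,CB,41.1
E,H,8.42
E,N,120.2
E,CA,56.6
E,CB,29.9
F,H,8.3
F,N,120.3
F,CA,57.7
F,CB,39.6
G,H,8.33
G,N,108.8
G,CA,45.1
H,H,8.42
H,N,118.2
H,CA,55.0
H,CB,29.0
I,H,8.0
I,N,119.9
I,CA,61.1
I,CB,38.8
K,H,8.29
K,N,120.4
K,CA,56.2
K,CB,33.1
L,H,8.16
L,N,121.8
L,CA,55.1
L,CB,42.4
M,H,8.28
M,N,119.6
M,CA,55.4
M,CB,32.9
N,H,8.4
N,N,118.7
N,CA,53.1
N,CB,38.9
P,N,136.8
P,CA,63.3
P,CB,32.1
Q,H,8.32
Q,N,119.8
Q,CA,55.7
Q,CB,29.4
R,H,8.23
R,N,120.5
R,CA,56.0
R,CB,30.9
S,H,8.31
S,N,115.7
S,CA,58.3
S,CB,63.8
T,H,8.15
T,N,113.6
T,CA,61.9
T,CB,69.8
V,H,8.03
V,N,119.2
V,CA,62.3
V,CB,32.9
W,H,8.25
W,N,121.3
W,CA,57.5
W,CB,29.6
Y,H,8.12
Y,N,120.3
Y,CA,57.9
Y,CB,38.8
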