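# Approximate conformation-specific shift centers of gravity (ppm),
# schema v1.  Columns: residue,nucleus,ss_class,shift.  Derived as
# random-coil value plus canonical secondary-shift offsets; NOT a
# published statistical table — substitute via CoGTable.from_csv.
residue,nucleus,ss_class,shift
A,H,helix,7.99
A,H,extended,8.54
A,N,helix,122.3
A,N,extended,125.6
A,CA,helix,55.3
A,CA,extended,51.1
A,CB,helix,18.5
A,CB,extended,21.6
C,H,helix,8.07
C,H,extended,8.62
C,N,helix,117.3
C,N,extended,120.6
C,CA,helix,61.0
C,CA,extended,56.8
C,CB,helix,27.4
C,CB,extended,30.5
D,H,helix,8.09
D,H,extended,8.64
D,N,helix,118.9
D,N,extended,122.2
D,CA,helix,57.0
D,CA,extended,52.8
D,CB,helix,40.5
D,CB,extended,43.6
E,H,helix,8.17
E,H,extended,8.72
E,N,helix,118.7
E,N,extended,122.0
E,CA,helix,59.4
E,CA,extended,55.2
E,CB,helix,29.3
E,CB,extended,32.4
F,H,helix,8.05
F,H,extended,8.6
F,N,helix,118.8
F,N,extended,122.1
F,CA,helix,60.5
F,CA,extended,56.3
F,CB,helix,39.0
F,CB,extended,42.1
G,H,helix,8.13
G,H,extended,8.57
G,N,helix,107.6
G,N,extended,110.24
G,CA,helix,46.5
G,CA,extended,44.4
H,H,helix,8.17
H,H,extended,8.72
H,N,helix,116.7
H,N,extended,120.0
H,CA,helix,57.8
H,CA,extended,53.6
H,CB,helix,28.4
H,CB,extended,31.5
I,H,helix,7.75
I,H,extended,8.3
I,N,helix,118.4
I,N,extended,121.7
I,CA,helix,63.9
I,CA,extended,59.7
I,CB,helix,38.2
I,CB,extended,41.3
K,H,helix,8.04
K,H,extended,8.59
K,N,helix,118.9
K,N,extended,122.2
K,CA,helix,59.0
K,CA,extended,54.8
K,CB,helix,32.5
K,CB,extended,35.6
L,H,helix,7.91
L,H,extended,8.46
L,N,helix,120.3
L,N,extended,123.6
L,CA,helix,57.9
L,CA,extended,53.7
L,CB,helix,41.8
L,CB,extended,44.9
M,H,helix,8.03
M,H,extended,8.58
M,N,helix,118.1
M,N,extended,121.4
M,CA,helix,58.2
M,CA,extended,54.0
M,CB,helix,32.3
M,CB,extended,35.4
N,H,helix,8.15
N,H,extended,8.7
N,N,helix,117.2
N,N,extended,120.5
N,CA,helix,55.9
N,CA,extended,51.7
N,CB,helix,38.3
N,CB,extended,41.4
P,N,helix,135.3
P,N,extended,138.6
P,CA,helix,66.1
P,CA,extended,61.9
P,CB,helix,31.5
P,CB,extended,34.6
Q,H,helix,8.07
Q,H,extended,8.62
Q,N,helix,118.3
Q,N,extended,121.6
Q,CA,helix,58.5
Q,CA,extended,54.3
Q,CB,helix,28.8
Q,CB,extended,31.9
R,H,helix,7.98
R,H,extended,8.53
R,N,helix,119.0
R,N,extended,122.3
R,CA,helix,58.8
R,CA,extended,54.6
R,CB,helix,30.3
R,CB,extended,33.4
S,H,helix,8.06
S,H,extended,8.61
S,N,helix,114.2
S,N,extended,117.5
S,CA,helix,61.1
S,CA,extended,56.9
S,CB,helix,63.2
S,CB,extended,66.3
T,H,helix,7.9
T,H,extended,8.45
T,N,helix,112.1
T,N,extended,115.4
T,CA,helix,64.7
T,CA,extended,60.5
T,CB,helix,69.2
T,CB,extended,72.3
V,H,helix,7.78
V,H,extended,8.33
V,N,helix,117.7
V,N,extended,121.0
V,CA,helix,65.1
V,CA,extended,60.9
V,CB,helix,32.3
V,CB,extended,35.4
W,H,helix,8.0
W,H,extended,8.55
W,N,helix,119.8
W,N,extended,123.1
W,CA,helix,60.3
W,CA,extended,56.1
W,CB,helix,29.0
W,CB,extended,32.1
Y,H,helix,7.87
Y,H,extended,8.42
Y,N,helix,118.8
Y,N,extended,122.1
Y,CA,helix,60.7
Y,CA,extended,56.5
Y,CB,helix,38.2
Y,CB,extended,41.3
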