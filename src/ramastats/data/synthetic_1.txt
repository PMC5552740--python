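# synthetic_1
   A  R  N  D  C  Q  E  G  H  I  L  K  M  F  P  S  T  W  Y  V
A  11  -2  -1  2  1  -4  -2  2  -4  2  -2  -2  1  -2  -3  -4  -1  2  -1  -1
R  -2  4  -3  -2  -3  1  -4  1  -4  1  -3  1  0  -2  2  1  0  0  -4  2
N  -1  -3  8  -1  -3  -3  1  -4  2  -4  0  -1  -2  0  0  -3  0  0  1  1
D  2  -2  -1  10  -3  2  -4  2  -3  -2  2  0  1  2  -1  -2  1  -1  1  -3
C  1  -3  -3  -3  7  -3  1  -3  2  -1  -3  -4  -3  -1  2  -3  -4  -2  -4  0
Q  -4  1  -3  2  -3  10  0  -4  -2  -3  2  -4  -1  -2  -3  1  -3  2  -4  2
E  -2  -4  1  -4  1  0  6  0  -2  1  -1  -1  2  0  -3  -3  -3  -2  -4  1
G  2  1  -4  2  -3  -4  0  4  -3  1  0  2  -2  2  -3  -4  -1  0  0  2
H  -4  -4  2  -3  2  -2  -2  -3  8  -2  -1  1  -2  2  0  -4  2  1  2  2
I  2  1  -4  -2  -1  -3  1  1  -2  5  -2  -2  1  2  2  2  -2  2  0  0
L  -2  -3  0  2  -3  2  -1  0  -1  -2  9  2  -1  2  -1  2  1  0  -4  2
K  -2  1  -1  0  -4  -4  -1  2  1  -2  2  8  -3  -2  2  -4  -2  -3  -3  2
M  1  0  -2  1  -3  -1  2  -2  -2  1  -1  -3  7  -4  -2  -3  -1  1  0  -1
F  -2  -2  0  2  -1  -2  0  2  2  2  2  -2  -4  8  -1  -2  -4  -3  -1  0
P  -3  2  0  -1  2  -3  -3  -3  0  2  -1  2  -2  -1  9  -2  1  1  0  -3
S  -4  1  -3  -2  -3  1  -3  -4  -4  2  2  -4  -3  -2  -2  11  1  -2  -4  2
T  -1  0  0  1  -4  -3  -3  -1  2  -2  1  -2  -1  -4  1  1  6  -2  0  -2
W  2  0  0  -1  -2  2  -2  0  1  2  0  -3  1  -3  1  -2  -2  4  -1  -4
Y  -1  -4  1  1  -4  -4  -4  0  2  0  -4  -3  0  -1  0  -4  0  -1  9  -3
V  -1  2  1  -3  0  2  1  2  2  0  2  2  -1  0  -3  2  -2  -4  -3  11
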