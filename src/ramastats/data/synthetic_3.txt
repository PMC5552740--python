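# synthetic_3
   A  R  N  D  C  Q  E  G  H  I  L  K  M  F  P  S  T  W  Y  V
A  4  -2  0  -3  -4  -3  -4  -1  0  2  1  -4  -2  -2  0  -1  0  1  -3  2
R  -2  11  -4  0  -4  -2  1  1  1  1  0  -3  -4  -2  0  1  2  -1  0  -1
N  0  -4  7  -1  -1  1  -1  -4  -4  -4  -2  2  -4  1  -2  -1  -3  2  -4  -3
D  -3  0  -1  10  -2  0  2  -3  0  -1  -3  0  -1  -4  -2  -4  2  -4  -4  0
C  -4  -4  -1  -2  7  -1  -2  2  -1  1  -2  -1  2  2  2  -3  -3  -3  -2  0
Q  -3  -2  1  0  -1  10  2  0  0  1  0  1  0  -4  -4  -2  2  0  -2  1
E  -4  1  -1  2  -2  2  11  -2  -1  0  2  -4  1  0  0  -4  1  -1  -3  -1
G  -1  1  -4  -3  2  0  -2  10  -2  -1  1  -4  0  -2  -2  0  -4  2  -3  0
H  0  1  -4  0  -1  0  -1  -2  8  0  -2  -4  1  -3  0  -2  2  -1  1  -3
I  2  1  -4  -1  1  1  0  -1  0  8  2  -2  0  0  1  -2  0  -3  -2  -1
L  1  0  -2  -3  -2  0  2  1  -2  2  7  -1  1  -3  -2  1  -2  -2  2  0
K  -4  -3  2  0  -1  1  -4  -4  -4  -2  -1  4  -1  -1  -3  -1  1  1  -2  2
M  -2  -4  -4  -1  2  0  1  0  1  0  1  -1  8  -1  -1  -3  1  2  0  -3
F  -2  -2  1  -4  2  -4  0  -2  -3  0  -3  -1  -1  11  -3  -4  -1  0  0  -2
P  0  0  -2  -2  2  -4  0  -2  0  1  -2  -3  -1  -3  10  2  1  0  1  2
S  -1  1  -1  -4  -3  -2  -4  0  -2  -2  1  -1  -3  -4  2  10  -4  -1  0  -4
T  0  2  -3  2  -3  2  1  -4  2  0  -2  1  1  -1  1  -4  4  2  -1  -1
W  1  -1  2  -4  -3  0  -1  2  -1  -3  -2  1  2  0  0  -1  2  7  -1  -4
Y  -3  0  -4  -4  -2  -2  -3  -3  1  -2  2  -2  0  0  1  0  -1  -1  10  2
V  2  -1  -3  0  0  1  -1  0  -3  -1  0  2  -3  -2  2  -4  -1  -4  2  5
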