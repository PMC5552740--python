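# synthetic_2
   A  R  N  D  C  Q  E  G  H  I  L  K  M  F  P  S  T  W  Y  V
A  5  0  1  2  0  1  1  -2  -4  -3  1  -3  -4  2  -1  -3  -4  -4  -4  -1
R  0  5  2  -2  2  -2  -2  -3  -1  -3  -1  -4  0  1  -3  -1  0  0  -3  -4
N  1  2  5  -2  -3  0  2  -1  -3  -1  -2  0  2  1  2  1  0  -3  -4  -3
D  2  -2  -2  4  -4  -2  1  2  -1  -1  -2  1  1  -3  1  -4  -2  1  -4  1
C  0  2  -3  -4  6  -4  -3  1  -1  -4  -2  -1  0  -3  0  -4  -3  -3  1  -2
Q  1  -2  0  -2  -4  7  -1  0  -2  -4  1  -1  1  -3  -1  1  2  1  -2  2
E  1  -2  2  1  -3  -1  9  -3  -2  -1  1  2  -3  -2  -4  2  2  -1  -1  2
G  -2  -3  -1  2  1  0  -3  8  -2  -2  -1  -4  -4  -2  -1  1  2  -1  1  2
H  -4  -1  -3  -1  -1  -2  -2  -2  11  2  -2  -4  -3  2  -4  -3  -4  1  0  1
I  -3  -3  -1  -1  -4  -4  -1  -2  2  7  1  -1  2  0  -3  -1  2  2  0  2
L  1  -1  -2  -2  -2  1  1  -1  -2  1  8  0  -4  1  -3  2  -1  2  -4  0
K  -3  -4  0  1  -1  -1  2  -4  -4  -1  0  6  -3  0  1  -2  2  2  -1  -3
M  -4  0  2  1  0  1  -3  -4  -3  2  -4  -3  5  -3  -4  -3  -4  0  0  -1
F  2  1  1  -3  -3  -3  -2  -2  2  0  1  0  -3  7  -2  -3  -2  -4  2  0
P  -1  -3  2  1  0  -1  -4  -1  -4  -3  -3  1  -4  -2  11  1  -2  -4  -3  -4
S  -3  -1  1  -4  -4  1  2  1  -3  -1  2  -2  -3  -3  1  6  1  1  -4  0
T  -4  0  0  -2  -3  2  2  2  -4  2  -1  2  -4  -2  -2  1  6  -3  -1  -2
W  -4  0  -3  1  -3  1  -1  -1  1  2  2  2  0  -4  -4  1  -3  9  -2  -2
Y  -4  -3  -4  -4  1  -2  -1  1  0  0  -4  -1  0  2  -3  -4  -1  -2  6  2
V  -1  -4  -3  1  -2  2  2  2  1  2  0  -3  -1  0  -4  0  -2  -2  2  4
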