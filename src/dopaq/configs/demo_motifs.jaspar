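>SYN0001 synTF1
A  [  2   2  24   2   2   2  24   2 ]
C  [  2   2   2  24   2  24   2   2 ]
G  [  2  24   2   2   2   2   2   2 ]
T  [ 24   2   2   2  24   2   2  24 ]
>SYN0002 synTF2
A  [ 24   2   2  24  24   2   2   2 ]
C  [  2  24   2   2   2   2  24   2 ]
G  [  2   2  24   2   2  24   2   2 ]
T  [  2   2   2   2   2   2   2  24 ]
>SYN0003 synTF3
A  [  2   2   2   2  24   2   2  24 ]
C  [ 24   2  24   2   2   2  24   2 ]
G  [  2  24   2  24   2  24   2   2 ]
T  [  2   2   2   2   2   2   2   2 ]
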