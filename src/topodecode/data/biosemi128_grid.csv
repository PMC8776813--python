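sensor,row,col,dropped
C30,0,0,0
C29,0,1,0
C28,0,2,0
C19,0,3,0
C18,0,4,0
C17,0,5,0
C15,0,6,0
C16,0,7,0
C8,0,8,0
C31,1,0,0
C32,1,1,0
C26,1,2,0
C27,1,3,0
C20,1,4,0
C14,1,5,0
C13,1,6,0
C10,1,7,0
C9,1,8,0
D6,2,0,0
D5,2,1,0
D4,2,2,0
C25,2,3,0
C21,2,4,0
C12,2,5,0
C4,2,6,0
C5,2,7,0
C6,2,8,0
D9,3,0,0
D3,3,1,0
C24,3,2,0
C23,3,3,0
C22,3,4,0
C11,3,5,0
C3,3,6,0
B28,3,7,0
B27,3,8,0
D11,4,0,0
D12,4,1,0
D13,4,2,0
D2,4,3,0
C2,4,4,0
B32,4,5,0
B31,4,6,0
B30,4,7,0
B29,4,8,0
D22,5,0,0
D21,5,1,0
D20,5,2,0
D1,5,3,0
C1,5,4,0
B23,5,5,0
B24,5,6,0
B25,5,7,0
B26,5,8,0
D18,6,0,0
D14,6,1,0
D15,6,2,0
A1,6,3,0
A2,6,4,0
B1,6,5,0
B20,6,6,0
B21,6,7,0
B22,6,8,0
D27,7,0,0
D28,7,1,0
D17,7,2,0
D16,7,3,0
B2,7,4,0
B19,7,5,0
B18,7,6,0
B17,7,7,0
B16,7,8,0
D25,8,0,0
D29,8,1,0
A6,8,2,0
A3,8,3,0
A4,8,4,0
B3,8,5,0
B13,8,6,0
B15,8,7,0
B14,8,8,0
D31,9,0,0
D30,9,1,0
A7,9,2,0
A5,9,3,0
A19,9,4,0
A32,9,5,0
B4,9,6,0
B12,9,7,0
B11,9,8,0
A9,10,0,0
A8,10,1,0
A18,10,2,0
A17,10,3,0
A20,10,4,0
A30,10,5,0
A31,10,6,0
B5,10,7,0
B6,10,8,0
A11,11,0,0
A10,11,1,0
A16,11,2,0
A21,11,3,0
A22,11,4,0
A29,11,5,0
B7,11,6,0
B8,11,7,0
B9,11,8,0
A13,12,0,0
A14,12,1,0
A15,12,2,0
A25,12,3,0
A24,12,4,0
A23,12,5,0
A28,12,6,0
A27,12,7,0
A26,12,8,0
D7,-1,-1,1
C7,-1,-1,1
D8,-1,-1,1
D10,-1,-1,1
D23,-1,-1,1
D19,-1,-1,1
D26,-1,-1,1
D24,-1,-1,1
B10,-1,-1,1
D32,-1,-1,1
A12,-1,-1,1
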