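Type	SBS1	SBS5	SBS15	SBS26	SBS44	SBSFLAT
A[C>A]A	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
A[C>A]C	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
A[C>A]G	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
A[C>A]T	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
C[C>A]A	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
C[C>A]C	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
C[C>A]G	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
C[C>A]T	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
G[C>A]A	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
G[C>A]C	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
G[C>A]G	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
G[C>A]T	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
T[C>A]A	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
T[C>A]C	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
T[C>A]G	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
T[C>A]T	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
A[C>G]A	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
A[C>G]C	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
A[C>G]G	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
A[C>G]T	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
C[C>G]A	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
C[C>G]C	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
C[C>G]G	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
C[C>G]T	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
G[C>G]A	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
G[C>G]C	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
G[C>G]G	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
G[C>G]T	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
T[C>G]A	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
T[C>G]C	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
T[C>G]G	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
T[C>G]T	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
A[C>T]A	0.00500000	0.01500000	0.02000000	0.00250000	0.14000000	0.01041667
A[C>T]C	0.00500000	0.01500000	0.02000000	0.00250000	0.01500000	0.01041667
A[C>T]G	0.37440000	0.01500000	0.03500000	0.00250000	0.04000000	0.01041667
A[C>T]T	0.00500000	0.01500000	0.02000000	0.00250000	0.01500000	0.01041667
C[C>T]A	0.00500000	0.01500000	0.02000000	0.00250000	0.01500000	0.01041667
C[C>T]C	0.00500000	0.01500000	0.02000000	0.00250000	0.01500000	0.01041667
C[C>T]G	0.21870000	0.01500000	0.07000000	0.00250000	0.05000000	0.01041667
C[C>T]T	0.00500000	0.01500000	0.02000000	0.00250000	0.01500000	0.01041667
G[C>T]A	0.00500000	0.01500000	0.10000000	0.00250000	0.10000000	0.01041667
G[C>T]C	0.00500000	0.01500000	0.06000000	0.00250000	0.07000000	0.01041667
G[C>T]G	0.19530000	0.01500000	0.21000000	0.00250000	0.18000000	0.01041667
G[C>T]T	0.00500000	0.01500000	0.08000000	0.00250000	0.07000000	0.01041667
T[C>T]A	0.00500000	0.01500000	0.02000000	0.00250000	0.01500000	0.01041667
T[C>T]C	0.00500000	0.01500000	0.02000000	0.00250000	0.01500000	0.01041667
T[C>T]G	0.11160000	0.01500000	0.03500000	0.00250000	0.03000000	0.01041667
T[C>T]T	0.00500000	0.01500000	0.02000000	0.00250000	0.01500000	0.01041667
A[T>A]A	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
A[T>A]C	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
A[T>A]G	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
A[T>A]T	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
C[T>A]A	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
C[T>A]C	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
C[T>A]G	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
C[T>A]T	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
G[T>A]A	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
G[T>A]C	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
G[T>A]G	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
G[T>A]T	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
T[T>A]A	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
T[T>A]C	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
T[T>A]G	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
T[T>A]T	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
A[T>C]A	0.00250000	0.01800000	0.01000000	0.05000000	0.00800000	0.01041667
A[T>C]C	0.00250000	0.01800000	0.01000000	0.05000000	0.00800000	0.01041667
A[T>C]G	0.00250000	0.01800000	0.01000000	0.05000000	0.00800000	0.01041667
A[T>C]T	0.00250000	0.01800000	0.01000000	0.05000000	0.00800000	0.01041667
C[T>C]A	0.00250000	0.01800000	0.01000000	0.05000000	0.00800000	0.01041667
C[T>C]C	0.00250000	0.01800000	0.01000000	0.05000000	0.00800000	0.01041667
C[T>C]G	0.00250000	0.01800000	0.01000000	0.05000000	0.00800000	0.01041667
C[T>C]T	0.00250000	0.01800000	0.01000000	0.05000000	0.00800000	0.01041667
G[T>C]A	0.00250000	0.01800000	0.01000000	0.05000000	0.00800000	0.01041667
G[T>C]C	0.00250000	0.01800000	0.01000000	0.05000000	0.00800000	0.01041667
G[T>C]G	0.00250000	0.01800000	0.01000000	0.05000000	0.00800000	0.01041667
G[T>C]T	0.00250000	0.01800000	0.01000000	0.05000000	0.00800000	0.01041667
T[T>C]A	0.00250000	0.01800000	0.01000000	0.05000000	0.00800000	0.01041667
T[T>C]C	0.00250000	0.01800000	0.01000000	0.05000000	0.00800000	0.01041667
T[T>C]G	0.00250000	0.01800000	0.01000000	0.05000000	0.00800000	0.01041667
T[T>C]T	0.00250000	0.01800000	0.01000000	0.05000000	0.00800000	0.01041667
A[T>G]A	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
A[T>G]C	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
A[T>G]G	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
A[T>G]T	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
C[T>G]A	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
C[T>G]C	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
C[T>G]G	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
C[T>G]T	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
G[T>G]A	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
G[T>G]C	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
G[T>G]G	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
G[T>G]T	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
T[T>G]A	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
T[T>G]C	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
T[T>G]G	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
T[T>G]T	0.00000000	0.00737500	0.00109375	0.00250000	0.00112500	0.01041667
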