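mutation_class	RefSig1	RefSig2	RefSig3	RefSig4	RefSig5
A[C>A]A	0.002525	0.101029	0.002525	0.001437	0.001437
A[C>A]C	0.002525	0.032069	0.002525	0.001437	0.001437
A[C>A]G	0.002525	0.052342	0.002525	0.001437	0.001437
A[C>A]T	0.002525	0.068149	0.002525	0.001437	0.001437
C[C>A]A	0.002525	0.052173	0.002525	0.001437	0.001437
C[C>A]C	0.002525	0.049831	0.002525	0.001437	0.001437
C[C>A]G	0.002525	0.028793	0.002525	0.001437	0.001437
C[C>A]T	0.002525	0.040351	0.002525	0.001437	0.001437
G[C>A]A	0.002525	0.054509	0.002525	0.001437	0.001437
G[C>A]C	0.002525	0.039558	0.002525	0.001437	0.001437
G[C>A]G	0.002525	0.042207	0.002525	0.001437	0.001437
G[C>A]T	0.002525	0.048705	0.002525	0.001437	0.001437
T[C>A]A	0.002525	0.025507	0.002525	0.001437	0.001437
T[C>A]C	0.002525	0.055315	0.002525	0.001437	0.001437
T[C>A]G	0.002525	0.086898	0.002525	0.001437	0.001437
T[C>A]T	0.002525	0.020561	0.002525	0.001437	0.001437
A[C>G]A	0.002525	0.002525	0.002525	0.005512	0.001437
A[C>G]C	0.002525	0.002525	0.002525	0.018594	0.001437
A[C>G]G	0.002525	0.002525	0.002525	0.007019	0.001437
A[C>G]T	0.002525	0.002525	0.002525	0.035715	0.001437
C[C>G]A	0.002525	0.002525	0.002525	0.007414	0.001437
C[C>G]C	0.002525	0.002525	0.002525	0.031436	0.001437
C[C>G]G	0.002525	0.002525	0.002525	0.059827	0.001437
C[C>G]T	0.002525	0.002525	0.002525	0.029457	0.001437
G[C>G]A	0.002525	0.002525	0.002525	0.011421	0.001437
G[C>G]C	0.002525	0.002525	0.002525	0.044321	0.001437
G[C>G]G	0.002525	0.002525	0.002525	0.044617	0.001437
G[C>G]T	0.002525	0.002525	0.002525	0.060481	0.001437
T[C>G]A	0.002525	0.002525	0.002525	0.028909	0.001437
T[C>G]C	0.002525	0.002525	0.002525	0.026185	0.001437
T[C>G]G	0.002525	0.002525	0.002525	0.018861	0.001437
T[C>G]T	0.002525	0.002525	0.002525	0.02425	0.001437
A[C>T]A	0.045621	0.002525	0.002525	0.001437	0.014211
A[C>T]C	0.028254	0.002525	0.002525	0.001437	0.004409
A[C>T]G	0.028699	0.002525	0.002525	0.001437	0.065426
A[C>T]T	0.015482	0.002525	0.002525	0.001437	0.014855
C[C>T]A	0.028372	0.002525	0.002525	0.001437	0.008719
C[C>T]C	0.073079	0.002525	0.002525	0.001437	0.031339
C[C>T]G	0.03354	0.002525	0.002525	0.001437	0.009785
C[C>T]T	0.100852	0.002525	0.002525	0.001437	0.018006
G[C>T]A	0.051431	0.002525	0.002525	0.001437	0.048544
G[C>T]C	0.136392	0.002525	0.002525	0.001437	0.037436
G[C>T]G	0.070181	0.002525	0.002525	0.001437	0.009741
G[C>T]T	0.020132	0.002525	0.002525	0.001437	0.058714
T[C>T]A	0.023791	0.002525	0.002525	0.001437	0.014086
T[C>T]C	0.03363	0.002525	0.002525	0.001437	0.039936
T[C>T]G	0.046041	0.002525	0.002525	0.001437	0.017103
T[C>T]T	0.0625	0.002525	0.002525	0.001437	0.061707
A[T>A]A	0.002525	0.002525	0.002525	0.035607	0.001437
A[T>A]C	0.002525	0.002525	0.002525	0.036544	0.001437
A[T>A]G	0.002525	0.002525	0.002525	0.013811	0.001437
A[T>A]T	0.002525	0.002525	0.002525	0.057154	0.001437
C[T>A]A	0.002525	0.002525	0.002525	0.034013	0.001437
C[T>A]C	0.002525	0.002525	0.002525	0.047461	0.001437
C[T>A]G	0.002525	0.002525	0.002525	0.003805	0.001437
C[T>A]T	0.002525	0.002525	0.002525	0.020475	0.001437
G[T>A]A	0.002525	0.002525	0.002525	0.023566	0.001437
G[T>A]C	0.002525	0.002525	0.002525	0.020983	0.001437
G[T>A]G	0.002525	0.002525	0.002525	0.043616	0.001437
G[T>A]T	0.002525	0.002525	0.002525	0.016144	0.001437
T[T>A]A	0.002525	0.002525	0.002525	0.014086	0.001437
T[T>A]C	0.002525	0.002525	0.002525	0.026438	0.001437
T[T>A]G	0.002525	0.002525	0.002525	0.029505	0.001437
T[T>A]T	0.002525	0.002525	0.002525	0.030811	0.001437
A[T>C]A	0.002525	0.002525	0.127319	0.001437	0.001437
A[T>C]C	0.002525	0.002525	0.047652	0.001437	0.001437
A[T>C]G	0.002525	0.002525	0.083333	0.001437	0.001437
A[T>C]T	0.002525	0.002525	0.037785	0.001437	0.001437
C[T>C]A	0.002525	0.002525	0.093705	0.001437	0.001437
C[T>C]C	0.002525	0.002525	0.01497	0.001437	0.001437
C[T>C]G	0.002525	0.002525	0.019817	0.001437	0.001437
C[T>C]T	0.002525	0.002525	0.041832	0.001437	0.001437
G[T>C]A	0.002525	0.002525	0.042851	0.001437	0.001437
G[T>C]C	0.002525	0.002525	0.027589	0.001437	0.001437
G[T>C]G	0.002525	0.002525	0.033948	0.001437	0.001437
G[T>C]T	0.002525	0.002525	0.009303	0.001437	0.001437
T[T>C]A	0.002525	0.002525	0.091581	0.001437	0.001437
T[T>C]C	0.002525	0.002525	0.006275	0.001437	0.001437
T[T>C]G	0.002525	0.002525	0.076845	0.001437	0.001437
T[T>C]T	0.002525	0.002525	0.043192	0.001437	0.001437
A[T>G]A	0.002525	0.002525	0.002525	0.001437	0.055938
A[T>G]C	0.002525	0.002525	0.002525	0.001437	0.029225
A[T>G]G	0.002525	0.002525	0.002525	0.001437	0.019192
A[T>G]T	0.002525	0.002525	0.002525	0.001437	0.014913
C[T>G]A	0.002525	0.002525	0.002525	0.001437	0.037869
C[T>G]C	0.002525	0.002525	0.002525	0.001437	0.015753
C[T>G]G	0.002525	0.002525	0.002525	0.001437	0.022501
C[T>G]T	0.002525	0.002525	0.002525	0.001437	0.012839
G[T>G]A	0.002525	0.002525	0.002525	0.001437	0.042099
G[T>G]C	0.002525	0.002525	0.002525	0.001437	0.021914
G[T>G]G	0.002525	0.002525	0.002525	0.001437	0.024902
G[T>G]T	0.002525	0.002525	0.002525	0.001437	0.016617
T[T>G]A	0.002525	0.002525	0.002525	0.001437	0.018716
T[T>G]C	0.002525	0.002525	0.002525	0.001437	0.02788
T[T>G]G	0.002525	0.002525	0.002525	0.001437	0.076413
T[T>G]T	0.002525	0.002525	0.002525	0.001437	0.017249
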