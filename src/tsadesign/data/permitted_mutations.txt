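# Permitted amino acids per design position of E. coli beta-glucuronidase,
# derived from family/superfamily alignment profiles (>=1 observation among
# beta-glucuronidases OR >=5% of ungapped glycosyl-hydrolase-family-2 rows).
162: A, C, F, G, H, I, L, M, N, Q, S, T, V, Y
163: C, D, F, G, K, M, Q, R, S, T, W
164: F, M, Q, W, Y
355: A, C, E, F, H, I, K, L, M, R, V, W, Y
356: A, C, D, E, F, G, H, I, L, M, N, Q, R, S, T, W, Y
361: A, D, E, F, G, H, I, K, L, M, N, Q, R, S, T, V, Y
362: A, D, F, G, I, K, M, N, R, S, T, V
549: A, C, G, K, L, R, T, W, Y
550: A, E, F, G, I, L, N, Q, S, T, V, Y
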