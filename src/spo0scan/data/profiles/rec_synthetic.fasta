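>OmpR_like
CLGFGMNIILMDDGMPKKSCIYSNCTQHTNLMPNPAGQDWWILEWFAYGTLYHYDDVVDHPLWGTRNNEICCCVMGCEFPEDYYDLKKGSDCTNAHGAQIWKMLNFQASKGFYWH
>RstA_like
PYGFGMNISNMDDGMPKWSCNTSNATQHTNMVLNPAGQDWDILEWFAYCTLYHYDDVQDHPLRGTPANPILCCVMGCFFPENYYDLKKHSNCINAHWAQIWKYLNFRAEKFFYWC
>CpxR_like
CLGFGDNCSWSDDWTPKTSCNYSNCTQETNCVPSPAKQDWDILEWFAYGQLYMYDDVVDHPLRGTFANPICCCVMGNDFPENYYDLKKHSDCWNAKGAQIHKMLFFRASKQFYDC
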