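>BsKinA synthetic stand-in construct
MGSSHHHHHHSSGLVPRGSHKNYPTHGCWYFWITKVPQNNDNIRYYAKFHNSSQAWSDDILTPAKMHIWHELTAPLGFEEQLWMHGGGVVTLAEGTLASYPRVCQENHPFNFLIGKDGTAYVPNPWGCIELPTRECLCWLQCPTANALAYHNWMEGGISD
>Bs0F synthetic stand-in construct
MGSSHHHHHHSSGLVPRGSHCATYTECVCNGFGMNISWMDDGWPKWSCNYSNCTQQTNLVPNTAGQDWDILEWFAYGTLYHYDDVVDQGWRILRAEPICACVMGCNFPENYYDLKKHSDCRNAHGAQIWLDLWFRASKVDYWWGRSWKPNGIQQKGASPTSWGSGMSG
>Bs0B synthetic stand-in construct
MGSSHHHHHHSSGLVPRGSHCRNQVDRIDHTLTILHGHSLDCNDMVRCLGNSPQAWSWDILTPAKMQIWHELQLPLGNYESLWMHMGGVATDAEGTLASILAPCQENFTFNFAIDKDGTAASPSLDVEQQQQFLETRFSFTTLWSYPVDDKQRWISFMIC
>Bs0A synthetic stand-in construct
MGSSHHHHHHSSGLVPRGSHKEAHGGRLCLGFGMNISWMDDGHPKWSCNYSNGTQHTNLVDNPAGQDAAILEWFAYGTLYHYDDVVDNELILLRAEPICCCVMGCGFPESPYDLKKHSDCINAHGAQIWKMLNFRASKYDYRCVQRADWVMWTCTDINIICIMDHWLG
>Dt1918 synthetic stand-in construct
MGSSHHHHHHSSGLVPRGSHDKNNMDYVEHWFWFCCQIVNPDVVSEVVMSNSPQAWSNDILTPAKMGIWHELTTPLGFEEQLWMHMGGVATDWVGTPASYPAPCQERFTSNFLIGKDGTADCENANCGPCRVTFITGLVGNYCSNSLWNCYAQGECRRMM
>Dt0F synthetic stand-in construct
MGSSHHHHHHSSGLVPRGSHITTSTKCCCLGFGMNISWMDDGMPKWSCNYSRPTQLTNLVPFKAGQDWDILEWFAKGTLYHYDDVVDQGLRILRAEPICICQMGCEFPEGYYDWKKHSDCINAHGAQIWKMLNFRASKVDYWCDCDTAVHEDEHCQQFSDYGDCPCMR
>Dt0B synthetic stand-in construct
MGSSHHHHHHSSGLVPRGSHHKKKCVTLGQPAMFPREYICLTPRYCAFIYNSPQAWTWDILTPAKMWIWHELQVDLGLEEQLWMHMGGVATDAEGTLASYPAPCQPNFTENFLIGKDGTARQNSNKASQFHRWPIIELKWGGNFDNEPDTCTTENPLHCE
>Dt0A synthetic stand-in construct
MGSSHHHHHHSSGLVPRGSHPNEYKNEPCLGFPLNISWMDDGMPSWSCNMQNCSQHTNLVPRPCGQDRDILEWFAPGTHYHYDDVVDNELRFLRADPICCCVMGCEFPRNYYDLKKHSDCIMAHGAQIWKMLNFPVSKFDDWCHHGRQISMAIIPNPRWATKQPAVYM
>Ca0903 synthetic stand-in construct
MGSSHHHHHHSSGLVPRGSHDMLGFDSWTNTWNTEMMVEEPMILVIGLYGNSIQAWSWDILTTAKMWICHELNIPLSAEMQLWMHMGGVATDAEGTVSSYPAPCQENFKFFFLIYKDGTACFSPAYATDDPANHNMLNEAGCILAWVVCFYYQTIWLMKH
>Ca3319 synthetic stand-in construct
MGSSHHHHHHSSGLVPRGSHTDHKGDNYVPFDRDRQHGQGVLILYQCARHNSPQAMSGDILTPAKLWIWHELSVPLGLEEQLMMHMLGVATDAEGTLWSYPAPCQEDFTFNFLIGKDGTTYDCQHGNVPNYMQGVDNLTMCPMKWNQWHLSDTDWGCEQP
>Ca0A synthetic stand-in construct
MGSSHHHHHHSSGLVPRGSHDEKYISTECLGFGMNISWWDDGMPKWSCNYSNCCQHTNLVPNPAGQDWDILEWFAYGQLYHYDDVVDNELRFIRADPICCCVMLCEFPENQYDLKKHDDCINAHNAQIWKMLTFRASKYDYWCLLWRRIAVICQALNNIFAWRPFVQM
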