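>LHR_TMD_SYNTHETIC start=356 (synthetic stand-in: printed residue identities at stated positions, filler elsewhere)
VGGLSGTLIIATGITITAIGLNLASLGGFSGFAGASFFSFIGMSNLIFADFTLATTLLVF
FTSVITLVFAIGVSFISAFGATFTTFVIFAISFSASIITFVLVTGIVERWSFGSSSTSTL
IVSSFVLVSFFGVTLWSGVLGIIMGSVVLVTLVAFISVLVAIVTISFTALVSIGLTSLTI
LAVAVIICSVSSILGATFAAVLVSTLATDLFFAFSMAATIITDVFCMGPVTVLSALSAFT
ILTSVSSALTTTVVTAVGINSSSNPFTYTIVLGSGAFITVLALGAFVGGGG
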