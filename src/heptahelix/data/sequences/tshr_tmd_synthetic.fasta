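>TSHR_TMD_SYNTHETIC start=409 (synthetic stand-in: printed residue identities at stated positions, filler elsewhere)
SILILGLSALISVFSVISTVGITNSVITTSAGASTAFLGAASFFLTNLFLGDVGIGIYLL
SSAVGGSAALVTIIFSIISWLSGGIVSAIFFVTVGVLVISVIALTSAITERWLTVAVGMA
AFAFVGSVAGTLAIAFGWLSLVSTTLIPASISSGTAGVSASFFTGAIVGLGISYTIGSGG
FLGIAFSVATIAYGIFSILVVFIGLILALKDGISSGRVGSLIFTDFFCMAPFSFYALTAT
ISGTITVSGSAFFLFILSALGNSVLNPAIYGTGFVIFSGAGSLGAGSGVFL
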