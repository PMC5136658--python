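>FSHR_TMD_SYNTHETIC start=360 (synthetic stand-in: printed residue identities at stated positions, filler elsewhere)
SIFLASAISFGAGIFSIFFFNLVAIILFSGLSTSIFTSFLIMANLATGDAVSIVVTAVIA
STLAFVIAVIFASSTSASLGGIFSFSSFITIVVLVGFFFVLVIILLERWLVGFAVFLTLG
AIGVIFGTVIGTTVWIVGGFLFLTTGLFGATFATIGGGAVVVFATGSATSALLVITIASG
VGAAGIILVALFFYGFSLTIGFSIGGGDGVLIARMAVLITTIASCMSPLIFVVALLTTGV
GASVLIGVIVIVFSFTTLGVINPVIYGFGIGIIFIAAITFSSFTGISGFGF
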