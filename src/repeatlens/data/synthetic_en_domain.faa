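>synthetic_EN_domain synthetic stand-in reference peptide for the LINE endonuclease domain
HTGVPGMFLSCPPEMPSWMALHMYNMLPAPCWIGGPWRFFPCWCDFGISFNAAMASTMPF
VHASGDPFRSPDALEVRDGGERPGIGVFTKNDPYVRYWASNMMWTGSCPFWVVDLFRIPK
TQNCTQDHWCSPHRCGYGYKHKPDYTKWQQVTATLDCRQVCSHMINSWDSTHQGETPKWW
VGRKIAPCTQECQPTEVYYE
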