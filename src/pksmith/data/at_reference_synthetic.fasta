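>at_reference_synthetic length=300 note=deterministic synthetic stand-in reference AT profile
FNRNTKWLQSDHKWPKKPWSTHRCWSTSPPDCVIHWRMRAELNQKRFREIDFQTCPVHVP
SACDLLHLGRWHGLIPFHVNVNHYQQLFMASWMHIDTRQCECRKFGIPNSWIWYIPYIEH
WVQTDDGHDNRLQQPLANFAEYCCDRKNTQIDCCNRHMKPKPRHTIKNKKTVTGEMHDPL
YLQIETDMHSMQSHYTQNSRPFPSLNTTEPKDSCFFKSEKCCGFIQAPNYPKKCVVKVAE
PKDPSYKHRNITAQPLCKYCNEEKFSGSHIQENWPVWRTYYHAYFCNFSVMELIMAACGH
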