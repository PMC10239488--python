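>synthetic_RT_domain synthetic stand-in reference peptide for the LINE reverse-transcriptase domain
FVKDVMSDEAQCTECKYNTHALPVVTTEGNPFYPDMMFEATVNVSSLAAKFIECVMQEAT
FELKGKFNKLKFRPQIECMRGAQKDLTKKRVDAQLRDKQNEMIFQSLIFGGLATSVDSSR
QHDIRLNQWGWIHIWWGINDWNEKDKGECKQMLSGKMGILDWKPRPVYSDSSQNPVWYSN
YQPDCRGWMWKQAVHCHHDMIISAPPGAAQNNWDAPPRSMHSCADVQGARNCKTPLQFPM
FDGCCEKQVY
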