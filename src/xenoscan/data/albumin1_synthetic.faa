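>albumin1_synthetic_1
QTPRVHRRLVPFHRTMFMTQIAKGLTDPCTAYQIAYCVTLSQDMWWFACSLDFPDCTVCKYVNEFYPVLVQTCAMGHGR
>albumin1_synthetic_2
WIHVREGQALYTAVLTMNNTEIPYFPFEYFCAQQYECAGYEFKHWGFCPDDTACDCPHSTGGDINHTQCPQGNS
>albumin1_synthetic_3
AMMMTLQSTQKHYLHASWSDFFTEGDSSSVSRCPQRPQCQEYMTYLIQHCTPHHCRCHGLNLIEVRASGCRLSNP
>albumin1_synthetic_4
RKFDNKKYITVTQKLPTFWMNMIAKSSWAGWQCGHRSNQHCYGDQTRVFNDFCKQPQCCMWIREHDEDTRSPCVFLI
>albumin1_synthetic_5
WALRKVIMPEIVAPDPRHDYGMTPKQNHTNCMQYRTCQLYIFFYLLCEITAHHCCNTAQRETDTPLPCDLHFEHM
>albumin1_synthetic_6
HVIGVAIIKQIWHQFNEFEIASHIWIERWIVCKNPIGCEFIVPESKDERCLDYGCRLCRKKQQPGWESSGWCDGPREA
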