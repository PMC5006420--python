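>toyRT1 synthetic DGR-like reverse transcriptase (test reference, not a natural sequence)
MTQPAELSTESTARSHLARLVVSHRVGIKVVQDKTSEFGSVLPQGFPLGLAREANSVGVE
HDNGSSEVTLGGTQQVDSACNIAHLINYYQPIPGKSHTALRVGQLSNAGSELQGRDILTD
WQWSQKRVTAEPIEYRSQFRDEHHLPKTHDLAEAILSNLSDPIKQGLQAKNIPDVMRESG
PQITEYADDFFSKPLRVYRIYGLRENLFYILGLYHNGNFIAVQTSKDTIMEQEGGDNKVL
IVSQECITV
>toyRT2 synthetic diverged relative of toyRT1 (~60%% identity, test reference)
MWQPNGISSNSTAYSHLARVVVSHCVMIKVRQSKASEFWIVLPQGYPKRLASEANWSLVE
HDFGSSRVTEIGCFHVDSATKIAHLIWSMQPYPGWSHTALCVGQNCNAGSFLHGRDTLGP
KIWSQKRVTAEPHEYRSQFRYEISLPKTHDLAEAILSGISDPIKQGHQAKNIPDVMTEKM
SQITEYADDFFSQPLVVARRYGNIENDFYRLGKYHQGKFIDVNTAKPTIMEQEGCDVKVM
IKCQECKNV
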