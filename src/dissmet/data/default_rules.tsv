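# Default biotransformation rule catalog: name <TAB> signed formula delta <TAB> class
# Deltas act element-wise on neutral compositions; applications that would
# drive any count negative are rejected.
demethylation	-CH2	methylation
methylation	+CH2	methylation
demethoxylation	-CH2O	cleavage
reduction	+H2	reduction
dehydrogenation	-H2	reduction
hydroxylation	+O	oxidation
dehydroxylation	-O	oxidation
hydration	+H2O	hydration
dehydration	-H2O	hydration
sinapoyl ester cleavage	-C11H10O4	cleavage
glycosidic bond cleavage	-C6H10O5	cleavage
C7H6 loss	-C7H6	cleavage
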