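# Synonym table for mitochondrial gene-name normalization (v1).
# Matching is case-insensitive after stripping spaces, hyphens and underscores.
# Extend at run time via Config/normalize_gene_name(extra=...).
synonym	normalized
cox1	COX1
coxi	COX1
co1	COX1
coi	COX1
cytochromecoxidasesubunit1	COX1
cytochromecoxidasesubuniti	COX1
cytochromeoxidasesubunit1	COX1
cox2	COX2
coxii	COX2
co2	COX2
coii	COX2
cytochromecoxidasesubunit2	COX2
cytochromecoxidasesubunitii	COX2
cox3	COX3
coxiii	COX3
co3	COX3
coiii	COX3
cytochromecoxidasesubunit3	COX3
cytochromecoxidasesubunitiii	COX3
cytb	CYTB
cob	CYTB
cytochromeb	CYTB
cytochromebapoenzyme	CYTB
nad1	NAD1
nd1	NAD1
nadhdehydrogenasesubunit1	NAD1
nad2	NAD2
nd2	NAD2
nadhdehydrogenasesubunit2	NAD2
nad3	NAD3
nd3	NAD3
nadhdehydrogenasesubunit3	NAD3
nad4	NAD4
nd4	NAD4
nadhdehydrogenasesubunit4	NAD4
nad4l	NAD4L
nd4l	NAD4L
nadhdehydrogenasesubunit4l	NAD4L
nad5	NAD5
nd5	NAD5
nadhdehydrogenasesubunit5	NAD5
nad6	NAD6
nd6	NAD6
nadhdehydrogenasesubunit6	NAD6
atp6	ATP6
atpase6	ATP6
atpsynthasef0subunit6	ATP6
atpsynthasefosubunit6	ATP6
atpasesubunit6	ATP6
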