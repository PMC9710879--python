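"""Shared vocabulary for the four-genotype double-heterozygote design."""

#: Closed set of genotype labels: wild type, the two single heterozygotes
#: (cohesin release factor Wapl, cohesin loader Nipbl) and the double
#: heterozygote carrying one loss-of-function allele at each locus.
GENOTYPES = ("WT", "WaplHet", "NipblHet", "Double")

#: Default replicate counts of the brain RNA-seq design emulated by the
#: synthetic generator (21 usable E17.5 samples).
DEFAULT_GROUP_SIZES = {"WT": 5, "WaplHet": 7, "NipblHet": 3, "Double": 6}
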