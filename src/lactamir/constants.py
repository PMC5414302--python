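"""Thresholds shared between the read simulator and the cleaning rules.

The cleaning rules are named after the removal steps of a standard
single-end small-RNA pipeline; the numeric thresholds behind the names are
deliberate defaults and every one of them can be overridden through
:class:`lactamir.preprocess.CleanParams`.  The simulator constructs its junk
reads against these same constants so that each rule has dedicated positive
cases.
"""

# Sanger / Phred+33 encoding throughout.
PHRED_OFFSET = 33

# A read is "low quality" when more than this fraction of its bases fall
# below LOW_QUALITY_PHRED.
LOW_QUALITY_PHRED = 20
LOW_QUALITY_MAX_FRACTION = 0.5

# A read is a 5' primer contaminant when its sequence starts with at least
# this many bases of the 5' adapter.
ADAPTER5_MIN_PREFIX = 12

# The 3' adapter is located by its leading ADAPTER3_MIN_PREFIX bases; a read
# in which that seed never occurs has no 3' adapter.
ADAPTER3_MIN_PREFIX = 8

# Poly(A) rule: at least this fraction of the trimmed insert is A.
POLY_A_FRACTION = 0.80

# Size selection: inserts outside this closed range are discarded.
MIN_INSERT_LEN = 18
MAX_INSERT_LEN = 30

# Illumina TruSeq small-RNA adapters (defaults only; any pair works).
DEFAULT_ADAPTER_3P = "TGGAATTCTCGGGTGCCAAGG"
DEFAULT_ADAPTER_5P = "GTTCAGAGTTCTACAGTCCGACGATC"

# Removal rules in the order they are applied; a read is attributed to the
# first rule it violates.  "overlong" enforces the upper end of the 18-30 nt
# size selection and is reported separately from the six named rules.
RULE_LOW_QUALITY = "low_quality"
RULE_ADAPTER5 = "adapter5_contaminant"
RULE_NO_ADAPTER3 = "no_adapter3"
RULE_POLY_A = "poly_a"
RULE_NO_INSERT = "no_insert"
RULE_TOO_SHORT = "too_short"
RULE_OVERLONG = "overlong"

RULE_ORDER = (
    RULE_LOW_QUALITY,
    RULE_ADAPTER5,
    RULE_NO_ADAPTER3,
    RULE_POLY_A,
    RULE_NO_INSERT,
    RULE_TOO_SHORT,
    RULE_OVERLONG,
)

# ncRNA contaminant classes, in classification priority order.
CONTAMINANT_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA", "scRNA", "srpRNA")
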