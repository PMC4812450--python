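"""Reported per-genome summaries for the captive Visayan warty pig cohort.

These are the published per-individual summary statistics from the
whole-genome resequencing of the two captive *Sus cebifrons* populations
(two Rotterdam-zoo individuals originating from Negros, five San-Diego-zoo
individuals from Panay) and of ten comparison *Sus* genomes, analysed with
the same ROH criteria.  They serve as worked-example inputs: the package's
cohort-summary and partition-accounting functions applied to these tables
must reproduce the reported cohort means (117 ± 51 ROHs overall, 142 ± 31
for Panay and 55 ± 29 for Negros; 1.9 / 2.2 / 1.3 Mb mean ROH length;
π = 12 vs 23 SNPs per 10-kb bin) and the shared/private totals.

π is nucleotide diversity outside ROHs in scaled SNPs per 10-kb bin;
``inbreeding_f`` is the studbook pedigree inbreeding coefficient.
"""

from __future__ import annotations

import pandas as pd

#: Per-individual genomic summaries for the seven S. cebifrons genomes.
CEBIFRONS = pd.DataFrame(
    [
        ("02M01", "negros", "M", 0.0, 34, 761.43, 12.5),
        ("02M02", "negros", "M", 0.0, 75, 1764.21, 12.1),
        ("01F01", "panay", "F", 0.1875, 110, 2245.32, 11.9),
        ("Kb16508", "panay", "M", 0.0625, 132, 1420.68, 12.4),
        ("Kb16637", "panay", "F", 0.0, 144, 1860.76, 12.4),
        ("Kb17528", "panay", "F", 0.25, 193, 2867.06, 12.0),
        ("Kb14130", "panay", "F", 0.0, 130, 2563.13, 12.2),
    ],
    columns=["sample", "island", "sex", "inbreeding_f", "n_rohs", "mean_roh_length_kb", "pi"],
)

#: The same summaries for the comparison Sus genomes (other species and
#: wild-boar / domestic populations), analysed with identical criteria.
OTHER_SUS = pd.DataFrame(
    [
        ("Sus verrucosus", 275, 3829.13, 6.3),
        ("Sus barbatus", 11, 1551.82, 26.4),
        ("Sus celebensis", 36, 2719.72, 23.2),
        ("Asian domestic", 271, 2796.31, 30.9),
        ("Asian wild boar 1", 155, 1966.39, 28.9),
        ("Asian wild boar 2", 44, 2120.00, 33.9),
        ("Asian wild boar (Japan)", 1172, 1573.41, 17.5),
        ("European domestic", 493, 1859.01, 28.4),
        ("European wild boar 1", 592, 1912.82, 16.2),
        ("European wild boar 2", 708, 1401.60, 18.4),
    ],
    columns=["sample", "n_rohs", "mean_roh_length_kb", "pi"],
)

#: Shared vs island-private counts per consequence class (MAC ≥ 2, fixed
#: differences against S. scrofa removed; Panay N=5, Negros N=2).
SHARED_PRIVATE = pd.DataFrame(
    {
        "shared": [3969361, 19565, 10081, 3370],
        "panay_private": [457741, 2150, 918, 343],
        "negros_private": [251910, 1190, 533, 171],
    },
    index=["all", "synonymous", "nonsyn_tolerated", "nonsyn_not_tolerated"],
)
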