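"""Published reference tables shipped with the package.

Currently the human internal-exon classification counts for the GENCODE
Release 43 basic annotation: unique internal exons of multi-exon
protein-coding genes, partitioned by coding type (Type 1-5) and splice
class (ASE / SSE / other alternative / constitutive).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: headline counts that go with the table
HUMAN_UNIQUE_INTERNAL_EXONS = 141_133
HUMAN_MULTI_EXON_CODING_GENES = 12_754


def human_internal_exon_counts() -> pd.DataFrame:
    """Human GENCODE v43 internal-exon counts (coding type x splice class).

    Rows Type1..Type5; columns Total, ASE, SSE, Other, Constitutive.
    """
    ref = resources.files("exon5uc.data").joinpath(
        "human_internal_exon_counts_gencode_v43.tsv"
    )
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", index_col="ExonClass")
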