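"""Bundled example data.

``load_published_ranking`` returns the second-stage variable-ranking table
from a published post-GWAS breast-cancer risk-profiling analysis of
postmenopausal women (25 variables: 13 CRP/IL-6-related SNPs and 12
lifestyle factors, ordered by minimal depth).  The columns are the
second-stage outputs of that analysis: minimal depth, permutation VIMP,
nested-model out-of-bag c-index and error, and the per-variable drop
error.  The table is used in documentation and as a worked example for the
drop-error arithmetic and the drop-error selection rule; it is *printed*
data, rounded to four decimals, not something this package recomputes.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_published_ranking"]


def load_published_ranking() -> pd.DataFrame:
    """Published second-stage ranking table (25 variables).

    Columns: ``variable``, ``minimal_depth``, ``vimp``, ``cindex``,
    ``error`` (nested-model OOB error, top-k models in row order) and
    ``drop_error`` (as printed in the source report).
    """
    with resources.files(__package__).joinpath("data/published_ranking.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
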