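"""Bundled reference tables.

``cml_hub_sign_patterns`` holds the published phase-contrast sign patterns of
the 24 consensus-network hub genes of the CML cohort this package targets
(calls at q <= 0.05 for accelerated-vs-chronic, blast-vs-accelerated and
blast-vs-chronic), together with their reported phase-behavior group.  It is
input data for the behavior classifier, not a computed result.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["cml_hub_sign_patterns"]

_HUB_ROWS = [
    # gene, s1 (AP vs CP), s2 (BC vs AP), s3 (BC vs CP), reported group
    ("ADD2", "=", "=", "-", "toward_blast_down"),
    ("CDCA3", "=", "=", "-", "toward_blast_down"),
    ("CTRB1", "=", "=", "-", "toward_blast_down"),
    ("ECEL1", "=", "=", "-", "toward_blast_down"),
    ("AURKB", "=", "-", "-", "toward_blast_down"),
    ("CEACAM6", "=", "-", "-", "toward_blast_down"),
    ("HLA-B", "=", "-", "-", "toward_blast_down"),
    ("INMT", "=", "-", "-", "toward_blast_down"),
    ("PRG3", "=", "-", "-", "toward_blast_down"),
    ("AZU1", "-", "-", "-", "toward_blast_down"),
    ("OPTN", "=", "=", "+", "toward_blast_up"),
    ("HLA-DMB", "=", "=", "+", "toward_blast_up"),
    ("NDUFAB1", "=", "=", "+", "toward_blast_up"),
    ("HLA-DRA", "=", "+", "+", "toward_blast_up"),
    ("EN1", "=", "-", "=", "accelerated_distinct"),
    ("MUC8", "=", "-", "=", "accelerated_distinct"),
    ("LOC389458", "-", "=", "-", "accelerated_distinct"),
    ("SPRR2A", "-", "=", "-", "accelerated_distinct"),
    ("TLX3", "-", "=", "-", "accelerated_distinct"),
    ("LOC284023", "-", "+", "-", "accelerated_distinct"),
    ("RHBDL1", "=", "+", "=", "accelerated_distinct"),
    ("RPL18A", "=", "+", "=", "accelerated_distinct"),
    ("PF4", "+", "=", "+", "accelerated_distinct"),
    ("TMEM40", "+", "=", "+", "accelerated_distinct"),
]


def cml_hub_sign_patterns() -> pd.DataFrame:
    """The 24 published hub genes with sign patterns and behavior groups."""
    return pd.DataFrame(
        _HUB_ROWS, columns=["gene", "s1", "s2", "s3", "group"]
    )
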