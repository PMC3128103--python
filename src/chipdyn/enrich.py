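"""Gene-set enrichment of target sets by hypergeometric test with
Benjamini–Hochberg correction.

Collections (motif modules, functional sets) arrive as named gene sets —
e.g. from a GMT file via :func:`chipdyn.io.read_gmt`.  Set members absent
from the universe are dropped (with a logged count) before testing, so the
test is always conditioned on the array's gene universe.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .types import ChipdynError
from .occupancy import overlap_hypergeometric

log = logging.getLogger(__name__)


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Step-up Benjamini–Hochberg adjusted q-values."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ChipdynError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def set_enrichment(
    targets: Iterable[str],
    collection: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of ``targets`` in each set of ``collection``.

    Returns one row per set: set size (within the universe), overlap k,
    upper-tail p (and log10 p), BH q across the collection, and a
    ``significant`` flag at ``q_threshold``.
    """
    if not collection:
        raise ChipdynError("enrichment needs a non-empty collection")
    uni = set(universe)
    tgt = set(targets)
    if not tgt <= uni:
        raise ChipdynError("targets must be a subset of the universe")
    rows = []
    for name, members in collection.items():
        members = set(members)
        outside = members - uni
        if outside:
            log.info("set %s: dropping %d gene(s) outside the universe", name, len(outside))
        members &= uni
        test = overlap_hypergeometric(members, tgt, uni)
        rows.append(
            {
                "set": name,
                "set_n": test.set_a_n,
                "overlap_k": test.overlap_k,
                "log10_p": test.log10_p,
                "p": 10.0 ** test.log10_p,
            }
        )
    table = pd.DataFrame(rows).set_index("set")
    table["q"] = bh_adjust(table["p"])
    table["significant"] = table["q"] < q_threshold
    return table
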