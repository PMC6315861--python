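"""Metabolite name normalization and the curated synonym table.

Non-targeted metabolomics reports and pathway databases rarely agree on
compound surface forms ("l-quinate" vs "quinate", "GPC" vs the full
glycerophosphocholine name, co-eluting tocopherol isomers reported as one
entity).  All joins in this package therefore go through a single
normalization step plus a curated synonym map, so that bookkeeping across
the abundance table, the annotation catalog and the gene map is stable.
"""

from __future__ import annotations

import re
import unicodedata

_WS = re.compile(r"\s+")

#: Canonical aliases, keyed by *normalized* surface form.  Values are the
#: canonical (normalized) metabolite IDs used throughout the package.
SYNONYMS: dict[str, str] = {
    "l-quinate": "quinate",
    "α-linolenate": "linolenate",
    "linolenate [alpha or gamma]": "linolenate",
    "cis-aconitate": "aconitate",
    "α-ketoglutarate (2-oxoglutarate)": "α-ketoglutarate",
    "2-oxoglutarate": "α-ketoglutarate",
    "glycerophosphorylcholin (sn-glycero-3-phosphocholine)": "glycerophosphorylcholine (gpc)",
    "glycerophosphorylcholine": "glycerophosphorylcholine (gpc)",
    "sn-glycero-3-phosphocholine": "glycerophosphorylcholine (gpc)",
    "gpc": "glycerophosphorylcholine (gpc)",
    # co-eluting vitamin E isomers are one reported entity
    "β-tocopherol": "γ-tocopherol/β-tocopherol",
    "γ-tocopherol": "γ-tocopherol/β-tocopherol",
    "glucosamine": "glucosaminate",
    "adenosine 5'-monophosphate": "adenosine 5'-monophosphate (amp)",
    "amp": "adenosine 5'-monophosphate (amp)",
    "n-acetyl-glutamate": "n-acetylglutamate",
    "4-hydroxyproline": "trans-4-hydroxyproline",
}


def normalize_name(name: str) -> str:
    """Normalize a metabolite surface form.

    Trims, case-folds, collapses internal whitespace, applies Unicode NFC,
    and maps typographic primes/dashes to their ASCII equivalents so that
    e.g. ``Adenosine 5′-monophosphate`` and ``adenosine 5'-monophosphate``
    compare equal.
    """
    s = unicodedata.normalize("NFC", name)
    s = s.replace("′", "'").replace("’", "'")
    s = s.replace("–", "-").replace("—", "-")
    s = _WS.sub(" ", s.strip())
    return s.casefold()


def resolve_name(name: str, synonyms: dict[str, str] | None = None) -> str:
    """Return the canonical metabolite ID for ``name``.

    ``synonyms`` overrides/extends the package table; keys and values are
    looked up post-normalization.  Resolution is applied repeatedly until a
    fixed point (alias chains are short and acyclic by construction).
    """
    table = SYNONYMS if synonyms is None else {**SYNONYMS, **synonyms}
    cur = normalize_name(name)
    seen = {cur}
    while cur in table:
        cur = normalize_name(table[cur])
        if cur in seen:  # defensive: malformed user-supplied alias cycle
            break
        seen.add(cur)
    return cur
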