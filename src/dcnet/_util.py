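"""Small shared helpers."""

from __future__ import annotations


def normalize_gene_id(gene: object) -> str:
    """Canonical gene identifier: stripped of surrounding whitespace, uppercased.

    Matching across the expression matrix, the PPI edge list and DEG tables is
    exact string equality after this normalization; no alias or ortholog
    resolution is attempted.
    """
    return str(gene).strip().upper()


def edge_key(a: str, b: str) -> tuple[str, str]:
    """Unordered gene pair as a sorted tuple (canonical edge identity)."""
    return (a, b) if a <= b else (b, a)
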