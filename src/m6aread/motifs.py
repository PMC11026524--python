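"""The six DRACH motifs targeted by the classifier, and motif normalization.

Motifs are stored in the DNA alphabet: RNA ``U`` is mapped to ``T`` on
ingestion so that e.g. ``GGACU`` and ``GGACT`` share one model. The central
base of every supported 5-mer is the methylatable adenosine.
"""

from __future__ import annotations

__all__ = ["SUPPORTED_MOTIFS", "normalize_motif", "require_supported_motif"]

#: The six most common DRACH contexts of m6A in human mRNA, DNA alphabet.
SUPPORTED_MOTIFS: tuple[str, ...] = (
    "AGACT",
    "GAACT",
    "GGACA",
    "GGACC",
    "GGACT",
    "TGACT",
)

_DNA = set("ACGT")


def normalize_motif(motif: str) -> str:
    """Return the canonical DNA-alphabet form of a 5-mer motif.

    Uppercases and maps U->T. Raises ``ValueError`` for anything that is not
    a 5-mer over {A, C, G, T, U} or whose central base is not A.
    """
    if not isinstance(motif, str):
        raise ValueError(f"motif must be a string, got {type(motif).__name__}")
    canon = motif.strip().upper().replace("U", "T")
    if len(canon) != 5 or not set(canon) <= _DNA:
        raise ValueError(f"motif {motif!r} is not a 5-mer over A/C/G/T/U")
    if canon[2] != "A":
        raise ValueError(f"motif {motif!r} does not have a central A")
    return canon


def require_supported_motif(motif: str) -> str:
    """Normalize ``motif`` and require it to be one of the six targets."""
    canon = normalize_motif(motif)
    if canon not in SUPPORTED_MOTIFS:
        raise ValueError(
            f"unsupported motif {motif!r}; supported motifs are "
            + ", ".join(SUPPORTED_MOTIFS)
        )
    return canon
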