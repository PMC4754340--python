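"""PWM LOD scoring of reference vs alternate alleles and splice-hexamer scanning.

A position weight matrix assigns each window the summed log-ratio of motif
base probability over background (the LOD).  Comparing the best LOD under
each allele of a SNP quantifies transcription-factor binding-site
disruption; a negative delta means the alternate allele weakens the best
match.  Splice-enhancer analysis is an exact-match scan of short hexamer
motifs against the two allele-resolved sequences of a template like
"CCCAG[G/T]AC".
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

from .errors import CoordinateError, ParameterError, TemplateError

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class PWM:
    """Positions x {A,C,G,T} probability matrix with background frequencies."""

    name: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.0

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ParameterError("probs must be positions x 4 (A,C,G,T)")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ParameterError("each PWM position must sum to 1")
        if not math.isclose(self.background.sum(), 1.0, abs_tol=1e-9):
            raise ParameterError("background frequencies must sum to 1")
        if (self.probs <= 0).any() or (self.background <= 0).any():
            raise ParameterError("probabilities must be strictly positive (use a pseudocount)")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @classmethod
    def from_counts(
        cls, name: str, counts: np.ndarray, pseudocount: float = 0.25, background=None
    ) -> "PWM":
        """Convert a positions x 4 count matrix to probabilities with an additive pseudocount."""
        counts = np.asarray(counts, dtype=float)
        if (counts < 0).any():
            raise ParameterError("counts must be non-negative")
        padded = counts + pseudocount
        probs = padded / padded.sum(axis=1, keepdims=True)
        bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
        return cls(name, probs, bg, pseudocount)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def lod(self, window: str, log_base: float = 2.0) -> float:
        """Summed log(p/background) over a window of the motif's length."""
        if len(window) != len(self):
            raise ParameterError("window length must equal motif length")
        idx = _encode(window)
        ratios = self.probs[np.arange(len(self)), idx] / self.background[idx]
        return float(np.sum(np.log(ratios) / math.log(log_base)))


@dataclass
class MotifHit:
    motif: str
    offset: int  # 0-based start in the query sequence
    strand: str  # '+' or '-'
    lod: float


@dataclass
class AlleleDisruption:
    snp_offset: int
    ref_best_lod: float
    alt_best_lod: float

    @property
    def delta(self) -> float:
        return self.alt_best_lod - self.ref_best_lod


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[b] for b in seq], dtype=int)
    except KeyError as e:
        raise ParameterError(f"non-ACGT character {e.args[0]!r} in sequence") from None


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def pwm_lod_scan(
    seq: str, pwm: PWM, both_strands: bool = True, log_base: float = 2.0
) -> list[MotifHit]:
    """LOD at every offset (and strand), sorted by LOD descending.

    A minus-strand hit at offset o scores the reverse complement of
    seq[o : o+L]; offsets always refer to the forward query.
    """
    seq = seq.upper()
    _encode(seq)  # validate alphabet
    L = len(pwm)
    if len(seq) < L:
        return []
    hits = []
    for o in range(len(seq) - L + 1):
        window = seq[o : o + L]
        hits.append(MotifHit(pwm.name, o, "+", pwm.lod(window, log_base)))
        if both_strands:
            hits.append(MotifHit(pwm.name, o, "-", pwm.lod(reverse_complement(window), log_base)))
    hits.sort(key=lambda h: (-h.lod, h.offset, h.strand))
    return hits


def allele_disruption(
    seq: str,
    snp_offset: int,
    ref: str,
    alt: str,
    pwm: PWM,
    both_strands: bool = True,
    log_base: float = 2.0,
) -> AlleleDisruption:
    """Best-LOD comparison of the two allele-substituted windows.

    Only offsets overlapping the SNP position contribute, so the delta
    isolates the allele's effect on motif strength.
    """
    seq = seq.upper()
    ref, alt = ref.upper(), alt.upper()
    if not (0 <= snp_offset < len(seq)):
        raise CoordinateError("snp_offset outside the sequence window")
    if seq[snp_offset] != ref:
        raise CoordinateError(
            f"reference mismatch: sequence has {seq[snp_offset]!r} at offset {snp_offset}, expected {ref!r}"
        )
    L = len(pwm)

    def best(allele: str) -> float:
        s = seq[:snp_offset] + allele + seq[snp_offset + 1 :]
        hits = pwm_lod_scan(s, pwm, both_strands, log_base)
        spanning = [h for h in hits if h.offset <= snp_offset < h.offset + L]
        if not spanning:
            return float("-inf")
        return max(h.lod for h in spanning)

    return AlleleDisruption(snp_offset, best(ref), best(alt))


_TEMPLATE_RE = re.compile(r"\[([ACGT])/([ACGT])\]")


def resolve_template(seq_template: str) -> tuple[dict[str, str], int]:
    """Expand a one-slot allele template into {allele: sequence} plus the slot offset."""
    template = seq_template.upper()
    slots = list(_TEMPLATE_RE.finditer(template))
    if len(slots) != 1:
        raise TemplateError(f"template must contain exactly one [X/Y] allele slot, found {len(slots)}")
    m = slots[0]
    prefix, suffix = template[: m.start()], template[m.end() :]
    _encode(prefix + suffix)
    offset = len(prefix)
    return {m.group(1): prefix + m.group(1) + suffix, m.group(2): prefix + m.group(2) + suffix}, offset


def splice_hexamer_scan(seq_template: str, motifs: set[str]) -> dict[str, list[MotifHit]]:
    """Exact-match scan of splice-enhancer motifs against each allele-resolved sequence.

    Returns {allele: hits}; hits may overlap one another and the allele
    position.  Motifs are matched on the forward strand only (splicing
    elements are strand-specific).
    """
    if not motifs:
        raise ParameterError("motif set must be non-empty")
    for m in motifs:
        _encode(m.upper())
    resolved, _ = resolve_template(seq_template)
    out: dict[str, list[MotifHit]] = {}
    for allele, seq in resolved.items():
        hits = []
        for motif in sorted(motifs):
            motif = motif.upper()
            start = seq.find(motif)
            while start != -1:
                hits.append(MotifHit(motif, start, "+", 0.0))  # exact match; no LOD
                start = seq.find(motif, start + 1)
        hits.sort(key=lambda h: (h.offset, h.motif))
        out[allele] = hits
    return out
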