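"""Synthetic labelled datasets with secretory / cytoplasmic class structure.

The generator emulates the compositional differences that separate
bacterial Sec-secretory sequences from cytoplasmic ones:

* secretory entries = a signal peptide (positively charged n-region, a
  hydrophobic h-region, an A-x-A style c-region; random length 18-25, the
  cleavage position is recorded) followed by a biased mature region —
  hydrophobics (L, I, V, F) and Arg depleted in mature positions 1-15,
  polar/hydroxyl residues (S, T, N, Q, Y, D) enriched in positions 16-80;
* cytoplasmic entries = background with a planted N-terminal hydrophobic
  stretch and a downstream K/R-enriched region;
* chimeras = a valid signal peptide fused to a secretion-incompatible
  downstream region (cytoplasmic-style tail, or a basic insertion in the
  early mature domain), labelled ``non_secretory``.

Per-position residue probabilities are softmax-tilted away from the
background: p ∝ background * exp(effect * bias).  The ``effect``
multiplier scales every bias, so effect = 0 makes both classes draws from
the identical background (exact exchangeability for null calibration).
All sequences start with Met.  Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .seqio import AA20, SequenceRecord, write_fasta, write_labels

_AA_INDEX = {a: i for i, a in enumerate(AA20)}


def _bias_vector(residues: str, value: float) -> np.ndarray:
    v = np.zeros(20)
    for r in residues:
        v[_AA_INDEX[r]] = value
    return v


@dataclass
class GeneratorSpec:
    n_secretory: int = 200
    n_cytoplasmic: int = 200
    seed: int = 0
    effect: float = 1.0

    # signal peptide
    sp_len_range: tuple = (18, 25)
    n_region_basic: int = 2  # K/R residues after the initial Met
    sp_basic_bias: float = 3.0
    sp_hydrophobic: str = "LAVIF"
    sp_hydrophobic_bias: float = 3.0
    c_motif_bias: float = 3.0  # A-x-A preference at the c-region

    # mature-domain biases (positions relative to cleavage)
    mature_depleted: str = "LIVFR"
    mature_depletion_bias: float = -1.5
    mature_early_span: int = 15
    mature_nterm_gly_span: int = 8  # Gly enrichment at the extreme N-terminus
    mature_nterm_gly_bias: float = 1.5
    mature_enriched: str = "STNQYD"
    mature_enrichment_bias: float = 1.2
    mature_enriched_span: int = 80

    # cytoplasmic biases: a SHORT hydrophobic stretch within the first 15
    # residues (distinctly shorter than a signal-peptide h-region)
    cyt_stretch_prob: float = 0.8
    cyt_stretch_len_range: tuple = (4, 7)
    cyt_stretch_residues: str = "LIVF"
    cyt_stretch_bias: float = 2.0
    cyt_downstream_basic: str = "KR"
    cyt_downstream_bias: float = 1.2
    cyt_downstream_span: int = 100
    # fraction of cytoplasmic chains retaining the initiator Met
    # (N-terminal methionine excision removes it from the rest)
    cyt_met_retained: float = 0.6

    length_range: tuple = (120, 400)
    background: Optional[np.ndarray] = None  # 20 probs, default uniform
    chimera_mode: str = "cytoplasmic_tail"  # or "basic_insertion"

    def __post_init__(self) -> None:
        if self.n_secretory < 0 or self.n_cytoplasmic < 0:
            raise ValueError("counts must be non-negative")
        if self.effect < 0:
            raise ValueError("effect size must be >= 0")
        if self.background is None:
            self.background = np.full(20, 0.05)
        self.background = np.asarray(self.background, dtype=np.float64)
        self.background = self.background / self.background.sum()


def background_from_records(records: Sequence[SequenceRecord]) -> np.ndarray:
    """Average residue composition of supplied sequences (for realistic
    backgrounds); non-standard residues ignored."""
    counts = np.zeros(20)
    for rec in records:
        for c in rec.seq:
            if c in _AA_INDEX:
                counts[_AA_INDEX[c]] += 1
    if counts.sum() == 0:
        raise ValueError("no standard residues in supplied records")
    return counts / counts.sum()


def _sample(rng: np.random.Generator, bias: np.ndarray, spec: GeneratorSpec) -> str:
    """Draw one residue per row of ``bias`` (rows are positions)."""
    logits = spec.effect * bias
    probs = spec.background[None, :] * np.exp(logits)
    probs /= probs.sum(axis=1, keepdims=True)
    u = rng.random(bias.shape[0])
    idx = (np.cumsum(probs, axis=1) < u[:, None]).sum(axis=1)
    return "".join(AA20[i] for i in idx)


def _signal_peptide_bias(spec: GeneratorSpec, sp_len: int) -> np.ndarray:
    """Per-position bias rows for signal-peptide positions 2..sp_len
    (position 1 is the fixed Met)."""
    rows = np.zeros((sp_len - 1, 20))
    k = 0
    for _ in range(spec.n_region_basic):  # n-region
        if k < rows.shape[0]:
            rows[k] = _bias_vector("KR", spec.sp_basic_bias)
            k += 1
    h_end = sp_len - 3  # 1-based position before the c-region
    while k < h_end - 1:  # h-region
        rows[k] = _bias_vector(spec.sp_hydrophobic, spec.sp_hydrophobic_bias)
        k += 1
    # c-region A-x-A: positions sp_len-2 and sp_len favour Ala
    for pos in (sp_len - 2, sp_len):
        row = pos - 2  # offset into rows (which start at position 2)
        if 0 <= row < rows.shape[0]:
            rows[row] = _bias_vector("A", spec.c_motif_bias)
    return rows


def _mature_bias(spec: GeneratorSpec, length: int) -> np.ndarray:
    rows = np.zeros((length, 20))
    early = min(spec.mature_early_span, length)
    rows[:early] = _bias_vector(spec.mature_depleted, spec.mature_depletion_bias)
    g = min(spec.mature_nterm_gly_span, length)
    rows[:g] += _bias_vector("G", spec.mature_nterm_gly_bias)
    upto = min(spec.mature_enriched_span, length)
    if upto > early:
        rows[early:upto] = _bias_vector(
            spec.mature_enriched, spec.mature_enrichment_bias
        )
    return rows


def _cytoplasmic_bias(spec: GeneratorSpec, length: int, rng) -> np.ndarray:
    # rows for positions 2..length+1 relative to the Met
    rows = np.zeros((length, 20))
    if rng.random() < spec.cyt_stretch_prob:
        lo, hi = spec.cyt_stretch_len_range
        sl = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(1, max(2, 14 - sl)))  # 0-based row after Met
        rows[start : start + sl] = _bias_vector(
            spec.cyt_stretch_residues, spec.cyt_stretch_bias
        )
        down_from = start + sl
    else:
        down_from = 10
    upto = min(spec.cyt_downstream_span, length)
    if upto > down_from:
        rows[down_from:upto] = _bias_vector(
            spec.cyt_downstream_basic, spec.cyt_downstream_bias
        )
    return rows


def _secretory_record(spec, rng, ident: str, downstream: str = "secretory") -> SequenceRecord:
    sp_len = int(rng.integers(spec.sp_len_range[0], spec.sp_len_range[1] + 1))
    total = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
    mature_len = max(total - sp_len, spec.mature_enriched_span)
    sp = "M" + _sample(rng, _signal_peptide_bias(spec, sp_len), spec)

    if downstream == "secretory":
        bias = _mature_bias(spec, mature_len)
    elif downstream == "cytoplasmic_tail":
        bias = _cytoplasmic_bias(spec, mature_len, rng)
    elif downstream == "basic_insertion":
        bias = _mature_bias(spec, mature_len)
        bias[1:5] = _bias_vector("R", 4.0)  # +4 Arg at mature positions 2-5
    else:
        raise ValueError(f"unknown downstream mode {downstream!r}")
    mature = _sample(rng, bias, spec)
    label = "secretory" if downstream == "secretory" else "non_secretory"
    return SequenceRecord(ident, sp + mature, label, cleavage_pos=sp_len)


def _cytoplasmic_record(spec, rng, ident: str) -> SequenceRecord:
    total = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
    body = _sample(rng, _cytoplasmic_bias(spec, total - 1, rng), spec)
    # excision probability scales with the effect size so that effect = 0
    # keeps the two classes exactly exchangeable (every chain starts Met)
    p_met = 1.0 - min(spec.effect, 1.0) * (1.0 - spec.cyt_met_retained)
    start = "M" if rng.random() < p_met else ""
    return SequenceRecord(ident, start + body, "cytoplasmic")


def generate_records(spec: GeneratorSpec) -> list[SequenceRecord]:
    """Secretory then cytoplasmic records, reproducible from the seed."""
    rng = np.random.default_rng(spec.seed)
    records = [
        _secretory_record(spec, rng, f"sec{i + 1:04d}") for i in range(spec.n_secretory)
    ]
    records += [
        _cytoplasmic_record(spec, rng, f"cyt{i + 1:04d}")
        for i in range(spec.n_cytoplasmic)
    ]
    return records


def generate_chimeras(spec: GeneratorSpec, n: int) -> list[SequenceRecord]:
    """Signal peptides fused to secretion-incompatible downstream regions."""
    rng = np.random.default_rng(spec.seed + 1)
    return [
        _secretory_record(spec, rng, f"chi{i + 1:04d}", downstream=spec.chimera_mode)
        for i in range(n)
    ]


def mature_only_records(records: Sequence[SequenceRecord]) -> list[SequenceRecord]:
    """Strip signal peptides from secretory records: the bare mature domains
    (cleavage annotation removed, label left unknown)."""
    out = []
    for rec in records:
        if rec.label == "secretory" and rec.cleavage_pos is not None:
            out.append(SequenceRecord(f"{rec.id}_mat", rec.seq[rec.cleavage_pos :]))
    return out


def generate_dataset(spec: GeneratorSpec, out_prefix=None, chimeras: int = 0):
    """Records (+ optional chimeras) and, with ``out_prefix``, the files
    ``<prefix>.fasta`` and ``<prefix>.labels.tsv``."""
    records = generate_records(spec)
    if chimeras:
        records += generate_chimeras(spec, chimeras)
    if out_prefix is not None:
        write_fasta(records, f"{out_prefix}.fasta")
        write_labels(records, f"{out_prefix}.labels.tsv")
    return records
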