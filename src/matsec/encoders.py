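"""Sequence feature encoders.

Nine feature groups are computed from an N-terminal window:

1-4. position-specific binary encodings under four alternative residue
     groupings ("individual", "relaxed", "compact", "disorder_order");
5-7. overlapping k-mer fractions for k = 1, 2, 3 (residue, di-peptide and
     tri-peptide content);
8.   hydrophobicity-customised pseudo-amino-acid composition (cPseAAC):
     the 20 composition terms plus ``lam`` lag-correlation terms built from
     a single hydrophobicity property;
9.   folding-component energies from the interaction-energy model (see
     :mod:`matsec.energy`).

Binary encodings set bit (position i, group g) when the residue at window
position i belongs to group g; property groups may overlap, so several bits
can fire at one position.  Gaps and non-standard residues yield all-zero
columns and are excluded from all composition denominators.
"""

from __future__ import annotations

import itertools
import json
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .seqio import AA20, AA20_SET, GAP, Window

# Kyte-Doolittle hydropathy, the default cPseAAC property ("K/D")
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

HYDROPHOBICITY_SCALES = {"K/D": KYTE_DOOLITTLE}


@dataclass(frozen=True)
class EncodingScheme:
    """Named, ordered residue grouping used by a binary encoder.

    ``groups`` maps a display symbol (drawn verbatim in logos) to the residue
    set it covers.  Groups may overlap; the "individual" scheme is the 20
    singletons.
    """

    name: str
    groups: tuple[tuple[str, frozenset], ...]

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError(f"scheme {self.name!r}: empty group set")
        for sym, members in self.groups:
            if not members or not members <= AA20_SET:
                raise ValueError(
                    f"scheme {self.name!r}: group {sym!r} must be a non-empty "
                    "subset of the 20 standard residues"
                )

    @property
    def n_groups(self) -> int:
        return len(self.groups)


def _scheme(name: str, pairs: Sequence[tuple[str, str]]) -> EncodingScheme:
    return EncodingScheme(name, tuple((s, frozenset(m)) for s, m in pairs))


INDIVIDUAL = _scheme("individual", [(a, a) for a in AA20])

# Physicochemical groupings; symbols follow the logo convention
# (@ acidic, + basic, h/ph hydrophobic, b bulky-aromatic, o-/x hydroxyl,
# pol/q polar, sm/sml small).
RELAXED = _scheme(
    "relaxed",
    [
        ("@", "DE"),
        ("+", "KR"),
        ("sm", "AG"),
        ("h", "ILVM"),
        ("ph", "LIF"),
        ("o-", "TS"),
        ("pol", "NQC"),
        ("q", "NQH"),
    ],
)

COMPACT = _scheme(
    "compact",
    [
        ("@", "DE"),
        ("+", "KR"),
        ("sml", "VGAP"),
        ("h", "ILVM"),
        ("b", "YWF"),
        ("x", "YTS"),
    ],
)

# disorder-promoting / order-promoting / neutral partition
DISORDER_ORDER = _scheme(
    "disorder_order",
    [
        ("dis", "ARGQSPEK"),
        ("ord", "WCFIYVLN"),
        ("neu", "HMTD"),
    ],
)

SCHEMES = {
    "individual": INDIVIDUAL,
    "relaxed": RELAXED,
    "compact": COMPACT,
    "disorder_order": DISORDER_ORDER,
}


def scheme_from_config(name: str, mapping: dict[str, str]) -> EncodingScheme:
    """Build a scheme from a JSON-style symbol -> residue-string mapping."""
    return _scheme(name, list(mapping.items()))


def load_schemes(path) -> dict[str, EncodingScheme]:
    """Load encoding schemes from a JSON file {scheme: {symbol: residues}}."""
    with open(path) as fh:
        raw = json.load(fh)
    return {name: scheme_from_config(name, mapping) for name, mapping in raw.items()}


def encode_binary(window: Window, scheme: EncodingScheme) -> np.ndarray:
    """0/1 vector of length W x n_groups; bit (i,g) = residue i in group g."""
    W = window.length
    out = np.zeros(W * scheme.n_groups, dtype=np.float64)
    for i, res in enumerate(window.residues):
        if res == GAP or res not in AA20_SET:
            continue
        base = i * scheme.n_groups
        for g, (_, members) in enumerate(scheme.groups):
            if res in members:
                out[base + g] = 1.0
    return out


def binary_feature_names(W: int, scheme: EncodingScheme) -> list[str]:
    return [
        f"bin_{scheme.name}:pos{i + 1}:{sym}"
        for i in range(W)
        for sym, _ in scheme.groups
    ]


_AA_INDEX = {a: i for i, a in enumerate(AA20)}


def _segments(seq: str) -> list[str]:
    """Maximal runs of standard residues (gaps/non-standard codes break runs)."""
    return [s for s in re.split(f"[^{AA20}]+", seq) if s]


def kmer_fractions(seq: str, k: int) -> np.ndarray:
    """Overlapping k-mer fractions over the 20^k standard-residue k-mers.

    The denominator is the number of valid k-mer windows (L - k + 1 on a
    clean sequence); gaps and non-standard residues terminate k-mer windows.
    """
    if k not in (1, 2, 3):
        raise ValueError("k must be 1, 2 or 3")
    counts = np.zeros(20**k, dtype=np.float64)
    total = 0
    for seg in _segments(seq):
        for i in range(len(seg) - k + 1):
            idx = 0
            for c in seg[i : i + k]:
                idx = idx * 20 + _AA_INDEX[c]
            counts[idx] += 1
            total += 1
    if total == 0:
        raise ValueError(f"sequence too short for k={k} after removing gaps")
    return counts / total


def kmer_feature_names(k: int) -> list[str]:
    return ["kmer%d:%s" % (k, "".join(p)) for p in itertools.product(AA20, repeat=k)]


def standardized_scale(scale: dict[str, float]) -> np.ndarray:
    """Scale values in AA20 order, standardised to zero mean / unit variance."""
    v = np.array([scale[a] for a in AA20], dtype=np.float64)
    return (v - v.mean()) / v.std()


def cpseaac(
    seq: str,
    scale: str = "K/D",
    lam: int = 5,
    w: float = 0.05,
) -> np.ndarray:
    """Single-property type-I pseudo-amino-acid composition.

    Entries 1..20 are composition terms f_i / (1 + w * sum theta); entries
    21..20+lam are w * theta_j / (1 + w * sum theta), where theta_j is the
    mean squared difference of standardised hydrophobicity values at lag j.
    Entries are non-negative and sum to 1 for w >= 0.
    """
    clean = "".join(c for c in seq if c in AA20_SET)
    L = len(clean)
    if lam >= L:
        raise ValueError(f"lam={lam} must be smaller than usable length {L}")
    h = standardized_scale(HYDROPHOBICITY_SCALES[scale])
    vals = h[[_AA_INDEX[c] for c in clean]]
    f = np.zeros(20)
    for c in clean:
        f[_AA_INDEX[c]] += 1.0
    f /= L
    theta = np.array(
        [np.mean((vals[j:] - vals[:-j]) ** 2) for j in range(1, lam + 1)]
    )
    denom = 1.0 + w * theta.sum()
    return np.concatenate([f / denom, w * theta / denom])


def cpseaac_feature_names(scale: str = "K/D", lam: int = 5) -> list[str]:
    return [f"cpseaac:{a}" for a in AA20] + [
        f"cpseaac:{scale}.{j}" for j in range(1, lam + 1)
    ]


#: canonical order of the nine feature groups
ALL_GROUPS = (
    "bin_individual",
    "bin_relaxed",
    "bin_compact",
    "bin_disorder_order",
    "kmer1",
    "kmer2",
    "kmer3",
    "cpseaac",
    "fc",
)


@dataclass
class FeatureMatrix:
    """Samples x named features, with a per-group column manifest."""

    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    manifest: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.sample_ids), len(self.feature_names)):
            raise ValueError("value matrix shape disagrees with names/ids")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names are not unique")
        if self.manifest and sum(self.manifest.values()) != len(self.feature_names):
            raise ValueError("manifest column counts do not add up")

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(name)]


def build_feature_matrix(
    windows: Sequence[Window],
    groups: Optional[Sequence[str]] = None,
    energy_model=None,
    cpseaac_scale: str = "K/D",
    cpseaac_lam: int = 5,
    cpseaac_w: float = 0.05,
    schemes: Optional[dict[str, EncodingScheme]] = None,
) -> FeatureMatrix:
    """Assemble the selected feature groups into one named matrix.

    All windows must share kind and length.  Group columns are concatenated
    in the canonical :data:`ALL_GROUPS` order regardless of the order given.
    The ``fc`` group needs an energy model; when none is passed the bundled
    synthetic default is loaded.
    """
    if not windows:
        raise ValueError("no windows given")
    kinds = {w.kind for w in windows}
    if len(kinds) > 1:
        raise ValueError(f"mixed window kinds: {sorted(kinds)}")
    lengths = {w.length for w in windows}
    if len(lengths) > 1:
        raise ValueError("windows differ in length")
    W = windows[0].length

    selected = list(ALL_GROUPS) if groups is None else list(groups)
    unknown = [g for g in selected if g not in ALL_GROUPS]
    if unknown:
        raise ValueError(f"unknown feature group(s): {unknown}")
    selected = [g for g in ALL_GROUPS if g in selected]

    schemes = schemes or SCHEMES
    if "fc" in selected and energy_model is None:
        from .energy import default_energy_model

        energy_model = default_energy_model()

    blocks: list[np.ndarray] = []
    names: list[str] = []
    manifest: dict[str, int] = {}
    clean = [w.residues.rstrip(GAP) for w in windows]

    for group in selected:
        if group.startswith("bin_"):
            scheme = schemes[group[4:]]
            block = np.stack([encode_binary(w, scheme) for w in windows])
            gnames = binary_feature_names(W, scheme)
        elif group.startswith("kmer"):
            k = int(group[4])
            block = np.stack([kmer_fractions(s, k) for s in clean])
            gnames = kmer_feature_names(k)
        elif group == "cpseaac":
            block = np.stack(
                [cpseaac(s, cpseaac_scale, cpseaac_lam, cpseaac_w) for s in clean]
            )
            gnames = cpseaac_feature_names(cpseaac_scale, cpseaac_lam)
        else:  # fc
            from .energy import composition, folding_energies

            block = np.stack(
                [folding_energies(composition(s), energy_model).e for s in clean]
            )
            gnames = [f"fc:e{k + 1}" for k in range(20)]
        blocks.append(block)
        names.extend(gnames)
        manifest[group] = len(gnames)

    return FeatureMatrix(
        sample_ids=[w.source_id for w in windows],
        feature_names=names,
        values=np.hstack(blocks),
        manifest=manifest,
    )
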