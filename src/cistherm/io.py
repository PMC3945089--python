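"""Readers, writers and the shared spatial-axis data model.

Sequences are plain FASTA, motifs are plain-text count/frequency matrices
(one row per motif position, four whitespace-separated columns in A,C,G,T
order, optional ``>name`` header line), and spatial profiles are TSV tables
whose first column is the position along the axis (either a fraction in
[0, 1] or a percentage in [0, 100]) and whose remaining columns are
relative levels, one column per factor or per gene.

Coordinates are 0-based half-open everywhere, including BED output.
Axis positions are fractions of the anterior-posterior axis in [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

VALID_RESIDUES = frozenset("ACGTN")
ALPHABET = "ACGT"


class FormatError(ValueError):
    """Raised when an input file violates its expected format."""


@dataclass
class Sequence:
    """A named DNA sequence over {A, C, G, T, N}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise FormatError(f"sequence {self.id!r} is empty")
        self.residues = self.residues.upper()
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise FormatError(
                f"sequence {self.id!r} contains illegal characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def has_n(self) -> bool:
        return "N" in self.residues


@dataclass
class PWM:
    """Position weight matrix: per-position base probabilities for one TF."""

    tf_name: str
    probs: np.ndarray  # (motif length, 4), rows sum to 1
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise FormatError(
                f"PWM {self.tf_name!r}: expected an (L, 4) matrix, "
                f"got shape {self.probs.shape}"
            )
        if np.any(self.probs <= 0):
            raise FormatError(
                f"PWM {self.tf_name!r}: zero/negative probabilities; "
                "apply a pseudocount"
            )
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise FormatError(f"PWM {self.tf_name!r}: rows do not sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise FormatError(f"PWM {self.tf_name!r}: background does not sum to 1")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in np.argmax(self.probs, axis=1))


@dataclass
class AxisProfile:
    """Relative level of something (TF concentration, expression) along the axis."""

    values: np.ndarray
    axis: np.ndarray  # fraction-of-axis coordinates, strictly increasing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        if self.values.shape != self.axis.shape or self.values.ndim != 1:
            raise ValueError("values and axis must be 1-D and equally long")
        if np.any(np.diff(self.axis) <= 0):
            raise ValueError("axis must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("profile values must be nonnegative")

    def __len__(self) -> int:
        return len(self.values)

    def same_grid(self, other: "AxisProfile") -> bool:
        return len(self) == len(other) and np.allclose(self.axis, other.axis)


@dataclass
class TFContext:
    """The trans environment: one concentration profile and one role per TF.

    Roles are fixed per TF: each factor acts either as an activator or as a
    repressor everywhere along the axis.
    """

    tf_names: list[str]
    profiles: list[AxisProfile]
    roles: list[str]  # 'activator' | 'repressor'

    def __post_init__(self) -> None:
        if not (len(self.tf_names) == len(self.profiles) == len(self.roles)):
            raise ValueError("tf_names, profiles and roles must align")
        for role in self.roles:
            if role not in ("activator", "repressor"):
                raise ValueError(f"unknown role {role!r}")
        ref = self.profiles[0]
        for p in self.profiles[1:]:
            if not ref.same_grid(p):
                raise ValueError("all TF profiles must share one axis grid")

    @property
    def axis(self) -> np.ndarray:
        return self.profiles[0].axis

    @property
    def n_bins(self) -> int:
        return len(self.profiles[0])

    def concentration_matrix(self) -> np.ndarray:
        """Per-TF concentrations, shape (n_tfs, n_bins)."""
        return np.stack([p.values for p in self.profiles])

    def index_of(self, tf: str) -> int:
        try:
            return self.tf_names.index(tf)
        except ValueError:
            raise KeyError(f"unknown TF {tf!r}") from None

    def with_knockdown(self, tf: str) -> "TFContext":
        """A copy of the context with one TF's concentration zeroed everywhere."""
        i = self.index_of(tf)
        profiles = list(self.profiles)
        profiles[i] = AxisProfile(np.zeros(self.n_bins), self.axis)
        return TFContext(list(self.tf_names), profiles, list(self.roles))


def read_fasta(path) -> list[Sequence]:
    """Read all records of a FASTA file, in file order, upper-cased."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return [Sequence(rec.id, str(rec.seq)) for rec in records]


def write_fasta(path, sequences: list[Sequence]) -> None:
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), 70):
                fh.write(seq.residues[i : i + 70] + "\n")


def _parse_pwm_blocks(path) -> list[tuple[str, list[list[float]]]]:
    blocks: list[tuple[str, list[list[float]]]] = []
    name, rows = None, []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                if rows:
                    blocks.append((name or f"motif_{len(blocks) + 1}", rows))
                name, rows = line[1:].split()[0], []
                continue
            fields = line.split()
            try:
                row = [float(x) for x in fields]
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric matrix entry")
            if len(row) != 4:
                raise FormatError(
                    f"{path}:{lineno}: expected 4 columns (A C G T), got {len(row)}"
                )
            rows.append(row)
    if rows:
        blocks.append((name or f"motif_{len(blocks) + 1}", rows))
    if not blocks:
        raise FormatError(f"{path}: no motif matrix found")
    return blocks


def pwm_from_counts(
    name: str,
    counts: np.ndarray,
    pseudocount: float = 0.5,
    background=None,
) -> PWM:
    """Normalise a count/frequency matrix row-wise into a PWM."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise FormatError(f"PWM {name!r}: negative counts")
    counts = counts + pseudocount
    rowsums = counts.sum(axis=1)
    if np.any(rowsums <= 0):
        raise FormatError(
            f"PWM {name!r}: all-zero count row with zero pseudocount"
        )
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return PWM(name, counts / rowsums[:, None], bg)


def read_pwms(path, pseudocount: float = 0.5, background=None) -> list[PWM]:
    """Read every motif of a plain-text count-matrix file."""
    return [
        pwm_from_counts(name, np.array(rows), pseudocount, background)
        for name, rows in _parse_pwm_blocks(path)
    ]


def read_pwm(path, pseudocount: float = 0.5, background=None) -> PWM:
    """Read a single-motif count-matrix file."""
    pwms = read_pwms(path, pseudocount, background)
    if len(pwms) != 1:
        raise FormatError(f"{path}: expected exactly one motif, found {len(pwms)}")
    return pwms[0]


def read_profile_table(path, roles: list[str] | None = None):
    """Read a TSV of axis-indexed profiles.

    The first column is the axis position, either as a fraction in [0, 1] or
    as a percentage (any value > 1.5 triggers the percent convention and a
    division by 100). One value column yields an :class:`AxisProfile`;
    several yield a :class:`TFContext` (roles default to activator unless
    given).
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need an axis column plus >= 1 value column")
    axis = df.iloc[:, 0].to_numpy(dtype=float)
    if np.any(np.diff(axis) <= 0):
        raise FormatError(f"{path}: axis positions must be strictly increasing")
    if axis.max() > 1.5:  # percent-of-axis convention
        axis = axis / 100.0
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    if np.any(values < 0):
        raise FormatError(f"{path}: negative profile values")
    profiles = [AxisProfile(values[:, j], axis) for j in range(values.shape[1])]
    if len(profiles) == 1:
        return profiles[0]
    names = list(df.columns[1:])
    if roles is None:
        roles = ["activator"] * len(names)
    return TFContext(names, profiles, roles)


def write_profile_table(path, profiles: dict[str, AxisProfile]) -> None:
    first = next(iter(profiles.values()))
    data = {"axis": first.axis}
    for name, p in profiles.items():
        if not p.same_grid(first):
            raise ValueError("profiles must share one grid")
        data[name] = p.values
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def resample_profile(p: AxisProfile, target_axis) -> AxisProfile:
    """Linearly interpolate a profile onto a new grid (no extrapolation)."""
    target_axis = np.asarray(target_axis, dtype=float)
    if target_axis.min() < p.axis[0] - 1e-12 or target_axis.max() > p.axis[-1] + 1e-12:
        raise ValueError("target axis extends beyond the profile's range")
    values = np.interp(target_axis, p.axis, p.values)
    return AxisProfile(np.clip(values, 0.0, None), target_axis)


def write_windows_bed(path, model_windows, chrom: str, locus_start: int = 0) -> None:
    """Write selected windows as BED6, scores scaled to the max weight.

    ``model_windows`` is a list of objects with ``start``/``length`` (bp,
    locus-relative, 0-based half-open) and optionally ``weight``.
    """
    if locus_start < 0:
        raise ValueError("locus_start must be nonnegative")
    windows = list(model_windows)
    weights = [float(getattr(w, "weight", 1.0)) for w in windows]
    wmax = max(weights) if weights else 1.0
    with open(path, "w") as fh:
        fh.write("# BED6: selected windows, score = 1000 * weight / max weight\n")
        for k, (w, weight) in enumerate(zip(windows, weights)):
            if w.start < 0:
                raise ValueError(f"window {k}: negative start coordinate")
            score = int(round(1000 * weight / wmax)) if wmax > 0 else 0
            fh.write(
                f"{chrom}\t{locus_start + w.start}\t{locus_start + w.start + w.length}"
                f"\twindow_{k}\t{score}\t.\n"
            )


def read_bed_intervals(path) -> list[tuple[int, int]]:
    """Read (start, end) pairs from a BED file (first three columns)."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: BED line with < 3 fields")
            intervals.append((int(fields[1]), int(fields[2])))
    return intervals


def save_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2)


def load_json(path):
    with open(path) as fh:
        return json.load(fh)
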