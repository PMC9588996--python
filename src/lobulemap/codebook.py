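"""Combinatorial barcode codebooks for multi-round, multi-channel FISH.

Each target gene is assigned a constant-weight binary code over the
``rounds x channels`` imaging grid: the gene's fluorescent signal is "on"
in exactly ``weight`` of the images.  A pool of *unused* codes is reserved
as decoys so that downstream decoding can estimate its false-positive rate
from the fraction of calls that land on a code no probe was designed for.

Bit order is round-major, channel-minor: bit ``r * channels + c`` is
round ``r`` (0-based), channel ``c``.  This order is fixed and is the
order in which image stacks are stacked into pixel profiles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from pathlib import Path

import numpy as np

__all__ = [
    "ImagingConfig",
    "Codebook",
    "build_codebook",
    "profile_length",
    "code_similarity",
]


@dataclass(frozen=True)
class ImagingConfig:
    """Geometry of the imaging experiment.

    Defaults follow the two-color, eight-round protocol in which every
    region yields 16 z-stacks and every pixel a 16-value profile.
    """

    rounds: int = 8
    channels: int = 2
    z_slices: int = 8
    pixel_size: float = 0.138  # micrometres per pixel

    def __post_init__(self) -> None:
        if self.rounds < 1 or self.channels < 1:
            raise ValueError("rounds and channels must be >= 1")
        if self.z_slices < 1:
            raise ValueError("z_slices must be >= 1")


def profile_length(config: ImagingConfig) -> int:
    """Length of a per-pixel intensity profile: one value per round x channel."""
    return config.rounds * config.channels


@dataclass
class Codebook:
    """Gene -> binary code map plus the reserved decoy codes.

    Invariants: all codes distinct, constant weight, pairwise Hamming
    distance >= ``min_distance``; used and unused sets are disjoint.
    """

    rounds: int
    channels: int
    codes: dict[str, np.ndarray]
    unused: list[np.ndarray] = field(default_factory=list)
    weight: int = 4
    min_distance: int = 4

    @property
    def n_bits(self) -> int:
        return self.rounds * self.channels

    @property
    def genes(self) -> list[str]:
        return list(self.codes)

    def all_codes(self) -> tuple[np.ndarray, list[str], np.ndarray]:
        """Stack used + unused codes.

        Returns ``(matrix, labels, is_used)`` where labels for decoys are
        ``"unused_<i>"``.  Row order (used genes in insertion order, then
        decoys) is the deterministic tie-break order for decoding.
        """
        mats = [self.codes[g] for g in self.codes] + list(self.unused)
        labels = list(self.codes) + [f"unused_{i}" for i in range(len(self.unused))]
        is_used = np.array([True] * len(self.codes) + [False] * len(self.unused))
        return np.asarray(mats, dtype=float), labels, is_used

    def validate(self) -> None:
        mat, _, _ = self.all_codes()
        if mat.shape[1] != self.n_bits:
            raise ValueError("code length does not match rounds * channels")
        if not np.all(mat.sum(axis=1) == self.weight):
            raise ValueError("codes are not constant-weight")
        n = len(mat)
        for i in range(n):
            for j in range(i + 1, n):
                if int(np.sum(mat[i] != mat[j])) < self.min_distance:
                    raise ValueError(
                        f"codes {i} and {j} violate min Hamming distance "
                        f"{self.min_distance}"
                    )

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "rounds": self.rounds,
            "channels": self.channels,
            "weight": self.weight,
            "min_distance": self.min_distance,
            "codes": {g: _bits_to_str(v) for g, v in self.codes.items()},
            "unused": [_bits_to_str(v) for v in self.unused],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Codebook":
        return cls(
            rounds=int(d["rounds"]),
            channels=int(d["channels"]),
            weight=int(d.get("weight", 4)),
            min_distance=int(d.get("min_distance", 4)),
            codes={g: _str_to_bits(s) for g, s in d["codes"].items()},
            unused=[_str_to_bits(s) for s in d.get("unused", [])],
        )

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def read_json(cls, path: str | Path) -> "Codebook":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _bits_to_str(v: np.ndarray) -> str:
    return "".join("1" if b else "0" for b in v)


def _str_to_bits(s: str) -> np.ndarray:
    return np.array([int(ch) for ch in s], dtype=np.int8)


def build_codebook(
    n_genes: int,
    config: ImagingConfig | None = None,
    *,
    gene_names: list[str] | None = None,
    weight: int = 4,
    min_distance: int = 4,
    n_unused: int = 8,
    seed: int = 0,
) -> Codebook:
    """Greedily select constant-weight codes at a minimum Hamming distance.

    All ``C(n_bits, weight)`` candidate codes are enumerated, shuffled
    reproducibly under ``seed``, and accepted in order unless closer than
    ``min_distance`` to an already-accepted code.  The first ``n_genes``
    accepted codes become gene codes; the next ``n_unused`` are reserved
    as decoys.

    Raises
    ------
    ValueError
        If the request exceeds the number of constant-weight codes, or the
        greedy pass cannot reach the requested count at this distance.
    """
    config = config or ImagingConfig()
    n_bits = profile_length(config)
    if weight < 1 or weight > n_bits:
        raise ValueError(f"weight must be in [1, {n_bits}]")
    capacity = comb(n_bits, weight)
    needed = n_genes + n_unused
    if needed > capacity:
        raise ValueError(
            f"requested {needed} codes but only C({n_bits},{weight})={capacity} "
            f"constant-weight-{weight} codes exist"
        )
    if gene_names is not None and len(gene_names) != n_genes:
        raise ValueError("gene_names length must equal n_genes")

    candidates = np.zeros((capacity, n_bits), dtype=np.int8)
    for i, on in enumerate(combinations(range(n_bits), weight)):
        candidates[i, list(on)] = 1
    rng = np.random.default_rng(seed)
    candidates = candidates[rng.permutation(capacity)]

    accepted: list[np.ndarray] = []
    acc_mat = np.zeros((0, n_bits), dtype=np.int8)
    for cand in candidates:
        if len(accepted) == needed:
            break
        if len(accepted) and int(np.min(np.sum(acc_mat != cand, axis=1))) < min_distance:
            continue
        accepted.append(cand)
        acc_mat = np.vstack([acc_mat, cand])
    if len(accepted) < needed:
        raise ValueError(
            f"could only place {len(accepted)} codes at Hamming distance "
            f">= {min_distance} (requested {needed}); lower min_distance or "
            f"the code count"
        )

    names = gene_names or [f"gene_{i:03d}" for i in range(n_genes)]
    return Codebook(
        rounds=config.rounds,
        channels=config.channels,
        codes={g: accepted[i] for i, g in enumerate(names)},
        unused=accepted[n_genes:needed],
        weight=weight,
        min_distance=min_distance,
    )


def code_similarity(profile: np.ndarray, code: np.ndarray) -> float:
    """Cosine similarity between a pixel profile and a binary code.

    Scale-invariant in the profile brightness: 1.0 iff the profile is a
    positive scalar multiple of the code (bright exactly on the on-bits,
    zero elsewhere).

    Raises
    ------
    ValueError
        On length mismatch or an all-zero profile (which has no direction
        and must be rejected upstream).
    """
    profile = np.asarray(profile, dtype=float)
    code = np.asarray(code, dtype=float)
    if profile.shape != code.shape:
        raise ValueError("profile and code lengths differ")
    pnorm = np.linalg.norm(profile)
    if pnorm == 0:
        raise ValueError("all-zero profile has undefined similarity")
    return float(profile @ code / (pnorm * np.linalg.norm(code)))
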