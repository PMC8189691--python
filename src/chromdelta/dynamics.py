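"""Chromatin-dynamics filtering of differential domains.

A differential chromatin domain (DCD) can contain heterogeneous state
changes. The dynamics filter extracts the subregions of each DCD where a
specific *directed* switch is observed, e.g. every replicate of group X
in an "enhancer on" state while every replicate of group Y is in an
"enhancer off" state. Such switch regions can be as short as a single
bin and are deliberately not annotated with an E-value: the local-score
statistics apply to the parent domain, not to arbitrary slices of it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dataset import Dataset, SampleGroup, StateAlphabet
from .errors import ValidationError
from .merge import MergedDomain

__all__ = ["LabelSet", "SwitchRegion", "dynamics_filter", "label_set_from_labels"]


@dataclass(frozen=True)
class LabelSet:
    """A named set of chromatin state indices (e.g. the 'enhancer on' states)."""

    name: str
    states: frozenset[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", frozenset(int(s) for s in self.states))
        if not self.states:
            raise ValidationError(f"label set {self.name!r} is empty")

    def validate_alphabet(self, alphabet: StateAlphabet) -> None:
        bad = [s for s in self.states if not 0 <= s < alphabet.size]
        if bad:
            raise ValidationError(
                f"label set {self.name!r} has states {sorted(bad)} outside alphabet"
            )

    def mask(self, size: int) -> np.ndarray:
        out = np.zeros(size, dtype=bool)
        out[list(self.states)] = True
        return out


def label_set_from_labels(alphabet: StateAlphabet, name: str, labels) -> LabelSet:
    """Build a label set from state labels (e.g. ``["E7", "E9"]``)."""
    return LabelSet(name, frozenset(alphabet.index(lab) for lab in labels))


@dataclass(frozen=True)
class SwitchRegion:
    """Maximal run of bins inside a DCD showing the requested switch."""

    chrom: str
    start: int
    end: int
    parent_domain_id: str
    direction: tuple[str, str]  # (label set satisfied by X, by Y)

    @property
    def n_bins(self) -> int:
        return self.end - self.start


def dynamics_filter(
    dcds: list[MergedDomain],
    dataset: Dataset,
    group_x: SampleGroup,
    group_y: SampleGroup,
    set_a: LabelSet,
    set_b: LabelSet,
    mode: str = "strict",
) -> list[SwitchRegion]:
    """Subregions of DCDs where group X sits in ``set_a`` and Y in ``set_b``.

    Parameters
    ----------
    mode
        ``"strict"`` requires every replicate's state to lie in the
        respective set at a bin; ``"majority"`` requires at least half of
        each group's replicates. Strict-mode regions are always contained
        in the corresponding majority-mode regions.

    Overlapping label sets are permitted but warned about, since a state
    in both sets makes the direction of the switch ambiguous.
    """
    if mode not in ("strict", "majority"):
        raise ValidationError(f"unknown consensus mode {mode!r}")
    set_a.validate_alphabet(dataset.alphabet)
    set_b.validate_alphabet(dataset.alphabet)
    if set_a.states & set_b.states:
        warnings.warn(
            f"label sets {set_a.name!r} and {set_b.name!r} overlap; "
            "switch direction is ambiguous for the shared states",
            stacklevel=2,
        )
    n = dataset.alphabet.size
    mask_a = set_a.mask(n)
    mask_b = set_b.mask(n)
    maps_x = dataset.group_maps(group_x)
    maps_y = dataset.group_maps(group_y)

    regions: list[SwitchRegion] = []
    for idx, dom in enumerate(dcds):
        domain_id = f"DCD_{idx + 1:05d}"
        in_a = np.stack(
            [mask_a[m.chrom_states[dom.chrom][dom.start:dom.end]] for m in maps_x]
        )
        in_b = np.stack(
            [mask_b[m.chrom_states[dom.chrom][dom.start:dom.end]] for m in maps_y]
        )
        if mode == "strict":
            ok = in_a.all(axis=0) & in_b.all(axis=0)
        else:
            ok = (in_a.mean(axis=0) >= 0.5) & (in_b.mean(axis=0) >= 0.5)
        for run_start, run_end in _true_runs(ok):
            regions.append(
                SwitchRegion(
                    chrom=dom.chrom,
                    start=dom.start + run_start,
                    end=dom.start + run_end,
                    parent_domain_id=domain_id,
                    direction=(set_a.name, set_b.name),
                )
            )
    return regions


def _true_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index ranges of maximal True runs."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return list(zip(starts.tolist(), ends.tolist()))
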