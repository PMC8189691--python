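"""Container for chromatin state segmentation data.

A :class:`Dataset` bundles everything one differential analysis needs:
the state alphabet, the segmentation model's emission probabilities, the
per-sample binned state maps and the sample-group metadata. All samples
must share one bin size and one set of chromosome lengths so that maps
are position-wise comparable. The container round-trips through a single
HDF5 file, which keeps an analysis reproducible from one artifact.

Coordinates are BED-style throughout: 0-based, half-open, bin-aligned.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .errors import InputError, ValidationError

__all__ = [
    "StateAlphabet",
    "EmissionMatrix",
    "SegmentationMap",
    "SampleGroup",
    "Dataset",
    "read_chrom_sizes",
    "read_segmentation",
    "read_emissions",
    "read_group_table",
    "build_dataset",
]

DEFAULT_BIN_SIZE = 200  # bp, ChromHMM convention

_STATE_DTYPE = np.uint16
_GAP = -1  # sentinel for uncovered bins during BED expansion


@dataclass(frozen=True)
class StateAlphabet:
    """Ordered alphabet of chromatin state labels.

    Parameters
    ----------
    labels
        Unique state identifiers in model order (e.g. ``("E1", ..., "E18")``).
    background_state
        Optional 0-based index of the background ("quiescent") state, the
        label emitted where no mark signal is detectable.
    functional_labels
        Optional mapping ``state label -> free-text annotation`` (e.g.
        ``"E7" -> "EnhA"``), used by the chromatin-dynamics filter.
    """

    labels: tuple[str, ...]
    background_state: int | None = None
    functional_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        if len(self.labels) < 2:
            raise ValidationError("alphabet needs at least two states")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("state labels must be unique")
        if self.background_state is not None and not (
            0 <= self.background_state < len(self.labels)
        ):
            raise ValidationError(
                f"background state index {self.background_state} outside alphabet"
            )
        unknown = set(self.functional_labels) - set(self.labels)
        if unknown:
            raise ValidationError(f"functional labels for unknown states: {sorted(unknown)}")

    @property
    def size(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(str(label))
        except ValueError:
            raise ValidationError(f"unknown state label {label!r}") from None

    def states_with_label(self, text: str) -> frozenset[int]:
        """All state indices whose functional label equals ``text``."""
        return frozenset(
            i for i, lab in enumerate(self.labels)
            if self.functional_labels.get(lab) == text
        )


@dataclass(frozen=True)
class EmissionMatrix:
    """Per-state emission probabilities of the segmentation model.

    ``probs[i, h]`` is the probability that state ``i`` emits mark ``h``.
    ChromHMM emissions are per-mark Bernoulli parameters, so rows need not
    sum to one; the scoring module normalises rows before computing
    entropies.
    """

    alphabet: StateAlphabet
    marks: tuple[str, ...]
    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=np.float64)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "marks", tuple(str(m) for m in self.marks))
        if probs.ndim != 2:
            raise ValidationError("emission probabilities must be a 2-D matrix")
        if len(self.marks) < 1:
            raise ValidationError("at least one mark required")
        if probs.shape != (self.alphabet.size, len(self.marks)):
            raise ValidationError(
                f"emission matrix shape {probs.shape} does not match "
                f"{self.alphabet.size} states x {len(self.marks)} marks"
            )
        if not np.all((probs >= 0.0) & (probs <= 1.0)):
            raise ValidationError("emission probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class SegmentationMap:
    """One sample's genome-wide chromatin state assignment at fixed bins.

    ``chrom_states`` maps chromosome name to an integer vector of state
    indices, one per bin.
    """

    sample_id: str
    bin_size: int
    chrom_states: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValidationError("bin size must be positive")
        if not self.chrom_states:
            raise ValidationError(f"sample {self.sample_id!r} has no chromosomes")
        states = {}
        for chrom, vec in self.chrom_states.items():
            arr = np.asarray(vec, dtype=_STATE_DTYPE)
            if arr.ndim != 1 or arr.size == 0:
                raise ValidationError(f"{chrom}: state vector must be non-empty 1-D")
            states[str(chrom)] = arr
        object.__setattr__(self, "chrom_states", states)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        """Number of bins per chromosome."""
        return {c: int(v.size) for c, v in self.chrom_states.items()}

    @property
    def n_bins(self) -> int:
        return sum(self.chrom_lengths.values())

    def validate_alphabet(self, alphabet: StateAlphabet) -> None:
        for chrom, vec in self.chrom_states.items():
            if vec.size and int(vec.max()) >= alphabet.size:
                raise ValidationError(
                    f"sample {self.sample_id!r}, {chrom}: state index "
                    f"{int(vec.max())} outside alphabet of size {alphabet.size}"
                )


@dataclass(frozen=True)
class SampleGroup:
    """A named, non-empty group of replicate sample ids."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(str(m) for m in self.members))
        if not self.members:
            raise ValidationError(f"group {self.name!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValidationError(f"group {self.name!r} lists a sample twice")


@dataclass
class Dataset:
    """Self-consistent bundle of maps, emissions and group metadata."""

    alphabet: StateAlphabet
    emissions: EmissionMatrix
    maps: dict[str, SegmentationMap]
    groups: dict[str, SampleGroup] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.maps:
            raise ValidationError("dataset needs at least one segmentation map")
        ref = next(iter(self.maps.values()))
        for sid, smap in self.maps.items():
            if sid != smap.sample_id:
                raise ValidationError(f"map key {sid!r} != sample_id {smap.sample_id!r}")
            if smap.bin_size != ref.bin_size:
                raise ValidationError("all samples must share one bin size")
            if smap.chrom_lengths != ref.chrom_lengths:
                raise ValidationError(
                    f"sample {sid!r} has chromosome lengths inconsistent with "
                    f"{ref.sample_id!r}"
                )
            smap.validate_alphabet(self.alphabet)
        for group in self.groups.values():
            missing = set(group.members) - set(self.maps)
            if missing:
                raise ValidationError(
                    f"group {group.name!r} references unknown samples {sorted(missing)}"
                )

    @property
    def bin_size(self) -> int:
        return next(iter(self.maps.values())).bin_size

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return next(iter(self.maps.values())).chrom_lengths

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.maps)

    def group(self, name: str) -> SampleGroup:
        try:
            return self.groups[name]
        except KeyError:
            raise ValidationError(f"unknown sample group {name!r}") from None

    def group_maps(self, group: SampleGroup) -> list[SegmentationMap]:
        return [self.maps[m] for m in group.members]

    # ------------------------------------------------------------------
    # HDF5 container
    # ------------------------------------------------------------------

    def save(self, path) -> None:
        """Write the dataset to a single HDF5 container file.

        The layout is fixed and datasets are written with ``track_times``
        disabled, so identical inputs produce identical files.
        """
        with h5py.File(path, "w", libver="earliest") as h5:
            _write_fixed(h5, "alphabet/labels", _str_array(self.alphabet.labels))
            h5["alphabet"].attrs["background_state"] = (
                -1 if self.alphabet.background_state is None
                else int(self.alphabet.background_state)
            )
            if self.alphabet.functional_labels:
                items = sorted(self.alphabet.functional_labels.items())
                _write_fixed(h5, "alphabet/functional_states",
                             _str_array([k for k, _ in items]))
                _write_fixed(h5, "alphabet/functional_texts",
                             _str_array([v for _, v in items]))
            _write_fixed(h5, "emissions/probs", self.emissions.probs)
            _write_fixed(h5, "emissions/marks", _str_array(self.emissions.marks))
            maps_grp = h5.create_group("maps")
            maps_grp.attrs["bin_size"] = int(self.bin_size)
            for sid in sorted(self.maps):
                smap = self.maps[sid]
                for chrom in sorted(smap.chrom_states):
                    _write_fixed(h5, f"maps/{sid}/{chrom}", smap.chrom_states[chrom])
            groups = {g.name: list(g.members) for g in self.groups.values()}
            meta = {"groups": groups, "metadata": self.metadata}
            _write_fixed(h5, "meta_json",
                         np.frombuffer(json.dumps(meta, sort_keys=True).encode(),
                                       dtype=np.uint8))

    @classmethod
    def load(cls, path) -> "Dataset":
        with h5py.File(path, "r") as h5:
            labels = [s.decode() for s in h5["alphabet/labels"][()]]
            bg = int(h5["alphabet"].attrs["background_state"])
            functional = {}
            if "alphabet/functional_states" in h5:
                keys = [s.decode() for s in h5["alphabet/functional_states"][()]]
                vals = [s.decode() for s in h5["alphabet/functional_texts"][()]]
                functional = dict(zip(keys, vals))
            alphabet = StateAlphabet(
                tuple(labels),
                background_state=None if bg < 0 else bg,
                functional_labels=functional,
            )
            emissions = EmissionMatrix(
                alphabet,
                tuple(s.decode() for s in h5["emissions/marks"][()]),
                h5["emissions/probs"][()],
            )
            bin_size = int(h5["maps"].attrs["bin_size"])
            maps = {}
            for sid in h5["maps"]:
                chrom_states = {c: h5[f"maps/{sid}/{c}"][()] for c in h5[f"maps/{sid}"]}
                maps[sid] = SegmentationMap(sid, bin_size, chrom_states)
            meta = json.loads(bytes(h5["meta_json"][()]).decode())
        groups = {
            name: SampleGroup(name, tuple(members))
            for name, members in meta["groups"].items()
        }
        return cls(alphabet, emissions, maps, groups, meta["metadata"])


def _str_array(values) -> np.ndarray:
    data = [str(v).encode() for v in values]
    width = max(len(d) for d in data)
    return np.array(data, dtype=f"S{max(width, 1)}")


def _write_fixed(h5: h5py.File, name: str, data: np.ndarray) -> None:
    h5.create_dataset(name, data=data, track_times=False)


# ----------------------------------------------------------------------
# Readers
# ----------------------------------------------------------------------


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length_bp`` table."""
    table = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"],
                        dtype={"chrom": str})
    if table.empty:
        raise InputError(f"{path}: empty chromosome sizes file")
    if table["chrom"].duplicated().any() or (table["size"] <= 0).any():
        raise InputError(f"{path}: chromosome sizes must be unique and positive")
    return dict(zip(table["chrom"], table["size"].astype(int)))


def read_segmentation(
    path,
    alphabet: StateAlphabet,
    bin_size: int = DEFAULT_BIN_SIZE,
    chrom_lengths: dict[str, int] | None = None,
    sample_id: str | None = None,
) -> SegmentationMap:
    """Read a ChromHMM-style segmentation BED into a per-bin state map.

    The file must be 4-column BED (chrom, start, end, state label),
    tab-separated, without header. Intervals must be non-overlapping and
    bin-aligned; the final interval of a chromosome may end at the (not
    necessarily bin-aligned) chromosome length. Uncovered bins are filled
    with the alphabet's background state; a gap without a declared
    background state is an error.

    Parameters
    ----------
    chrom_lengths
        Chromosome lengths in base pairs. When omitted, each chromosome is
        assumed to end with its last interval.
    """
    try:
        bed = pd.read_csv(
            path, sep="\t", header=None, usecols=[0, 1, 2, 3],
            names=["chrom", "start", "end", "state"],
            dtype={"chrom": str, "state": str},
        )
    except (ValueError, OSError) as exc:
        raise InputError(f"{path}: cannot parse segmentation BED ({exc})") from exc
    if bed.empty:
        raise InputError(f"{path}: empty segmentation file")

    label_to_idx = {lab: i for i, lab in enumerate(alphabet.labels)}
    unknown = set(bed["state"]) - set(label_to_idx)
    if unknown:
        raise InputError(f"{path}: unknown state labels {sorted(unknown)}")

    chrom_states: dict[str, np.ndarray] = {}
    for chrom, sub in bed.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy(dtype=np.int64)
        ends = sub["end"].to_numpy(dtype=np.int64)
        if np.any(starts >= ends) or starts[0] < 0:
            raise InputError(f"{path}: {chrom}: invalid interval bounds")
        if np.any(starts[1:] < ends[:-1]):
            raise InputError(f"{path}: {chrom}: overlapping intervals")
        size_bp = ends[-1] if chrom_lengths is None else int(chrom_lengths[chrom])
        if ends[-1] > size_bp:
            raise InputError(f"{path}: {chrom}: interval exceeds chromosome length")
        n_bins = math.ceil(size_bp / bin_size)
        if np.any(starts % bin_size):
            raise InputError(f"{path}: {chrom}: interval start not bin-aligned")
        # every end must be bin-aligned except an end flush with the chromosome
        misaligned = (ends % bin_size != 0) & (ends != size_bp)
        if np.any(misaligned):
            raise InputError(f"{path}: {chrom}: interval end not bin-aligned")

        vec = np.full(n_bins, _GAP, dtype=np.int32)
        bin_starts = starts // bin_size
        bin_ends = -(-ends // bin_size)  # ceil, covers a flush partial last bin
        for bs, be, lab in zip(bin_starts, bin_ends, sub["state"]):
            vec[bs:be] = label_to_idx[lab]
        if np.any(vec == _GAP):
            if alphabet.background_state is None:
                raise InputError(
                    f"{path}: {chrom}: coverage gap but no background state declared"
                )
            vec[vec == _GAP] = alphabet.background_state
        chrom_states[chrom] = vec.astype(_STATE_DTYPE)

    if chrom_lengths is not None:
        missing = set(chrom_lengths) - set(chrom_states)
        if missing:
            if alphabet.background_state is None:
                raise InputError(
                    f"{path}: chromosomes {sorted(missing)} absent and no "
                    "background state declared"
                )
            for chrom in missing:
                n_bins = math.ceil(chrom_lengths[chrom] / bin_size)
                chrom_states[chrom] = np.full(
                    n_bins, alphabet.background_state, dtype=_STATE_DTYPE
                )

    if sample_id is None:
        sample_id = _stem(path)
    return SegmentationMap(sample_id, bin_size, chrom_states)


def read_emissions(path, state_prefix: str = "E") -> EmissionMatrix:
    """Read a ChromHMM emissions table (TSV, header = marks, rows = states).

    The first column carries the state identifier; purely numeric
    identifiers ``k`` are turned into labels ``f"{state_prefix}{k}"`` so
    they match ChromHMM's segmentation output labels.
    """
    try:
        table = pd.read_csv(path, sep="\t", index_col=0)
    except (ValueError, OSError) as exc:
        raise InputError(f"{path}: cannot parse emissions table ({exc})") from exc
    if table.shape[0] < 2 or table.shape[1] < 1:
        raise InputError(f"{path}: emissions table needs >=2 states and >=1 mark")
    probs = table.to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(probs)) or probs.min() < 0 or probs.max() > 1:
        raise InputError(f"{path}: emission values must be probabilities in [0, 1]")
    labels = tuple(
        f"{state_prefix}{lab}" if str(lab).isdigit() else str(lab)
        for lab in table.index
    )
    alphabet = StateAlphabet(labels)
    return EmissionMatrix(alphabet, tuple(table.columns), probs)


def read_group_table(path) -> dict[str, SampleGroup]:
    """Read a two-column ``sample_id<TAB>group`` assignment table."""
    table = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"],
                        dtype=str)
    if table.empty or table["sample"].duplicated().any():
        raise InputError(f"{path}: group table empty or lists a sample twice")
    return {
        name: SampleGroup(name, tuple(sub["sample"]))
        for name, sub in table.groupby("group", sort=True)
    }


def build_dataset(
    maps: list[SegmentationMap],
    emissions: EmissionMatrix,
    groups: dict[str, SampleGroup] | None = None,
    metadata: dict | None = None,
) -> Dataset:
    """Assemble maps, emissions and metadata into one validated dataset."""
    if not maps:
        raise ValidationError("no segmentation maps supplied")
    seen: dict[str, SegmentationMap] = {}
    for smap in maps:
        if smap.sample_id in seen:
            raise ValidationError(f"duplicate sample id {smap.sample_id!r}")
        seen[smap.sample_id] = smap
    return Dataset(
        alphabet=emissions.alphabet,
        emissions=emissions,
        maps=seen,
        groups=dict(groups or {}),
        metadata=dict(metadata or {}),
    )


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]
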