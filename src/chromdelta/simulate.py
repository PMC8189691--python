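"""Synthetic chromatin-state datasets for testing and calibration.

The generator instantiates exactly the probabilistic model the
statistics assume: per-bin states drawn i.i.d. from configurable state
frequencies, emission matrices with Dirichlet rows, replicates produced
by copying a group template and flipping bins at a configurable rate,
and optional planted differential domains that overwrite a state pair
into all replicates of the two groups. Everything is deterministic
given the seed, so simulated datasets double as reproducible fixtures
for the full pipeline including the file-based input path.

Defaults mirror a typical ChromHMM-style setting: 18 states with the
last one acting as the quiescent background, 6 histone marks, 200 bp
bins, a background frequency of one half with the remaining mass spread
evenly, 1% replicate discordance and two replicates per group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import (
    Dataset,
    EmissionMatrix,
    SampleGroup,
    SegmentationMap,
    StateAlphabet,
    build_dataset,
)
from .errors import ValidationError
from .scoring import ScoreMatrix

__all__ = [
    "PlantedDomain",
    "SimConfig",
    "simulate_emissions",
    "simulate_groups",
    "max_score_state_pair",
    "write_chromhmm_files",
]


@dataclass(frozen=True)
class PlantedDomain:
    """A differential interval forced into the simulated maps."""

    chrom: str
    start: int
    end: int
    state_x: int
    state_y: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValidationError("planted interval must be non-empty")


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one synthetic dataset."""

    n_states: int = 18
    n_marks: int = 6
    bin_size: int = 200
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chrS1": 100_000}
    )  # bins per chromosome
    state_freqs: tuple[float, ...] | None = None  # None: background-heavy default
    replicate_noise: float = 0.01
    n_replicates: tuple[int, int] = (2, 2)
    background_state: int | None = None  # None: last state
    planted: tuple[PlantedDomain, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_states < 2:
            raise ValidationError("need at least two states")
        if not 0.0 <= self.replicate_noise < 1.0:
            raise ValidationError("replicate noise must be in [0, 1)")
        if min(self.n_replicates) < 1:
            raise ValidationError("each group needs at least one replicate")
        bg = self.background_state
        object.__setattr__(
            self, "background_state", self.n_states - 1 if bg is None else int(bg)
        )
        if not 0 <= self.background_state < self.n_states:
            raise ValidationError("background state outside alphabet")
        freqs = self.state_freqs
        if freqs is None:
            freqs = _default_freqs(self.n_states, self.background_state)
        freqs = tuple(float(f) for f in freqs)
        if len(freqs) != self.n_states or any(f < 0 for f in freqs):
            raise ValidationError("state frequencies must be a non-negative vector")
        if abs(sum(freqs) - 1.0) > 1e-9:
            raise ValidationError("state frequencies must sum to 1")
        object.__setattr__(self, "state_freqs", freqs)
        object.__setattr__(self, "planted", tuple(self.planted))
        seen: dict[str, list[tuple[int, int]]] = {}
        for dom in self.planted:
            if dom.chrom not in self.chrom_lengths:
                raise ValidationError(f"planted domain on unknown {dom.chrom!r}")
            if dom.end > self.chrom_lengths[dom.chrom]:
                raise ValidationError("planted domain exceeds chromosome")
            if not (
                0 <= dom.state_x < self.n_states and 0 <= dom.state_y < self.n_states
            ):
                raise ValidationError("planted state index outside alphabet")
            for a, b in seen.setdefault(dom.chrom, []):
                if dom.start < b and a < dom.end:
                    raise ValidationError("planted domains overlap")
            seen[dom.chrom].append((dom.start, dom.end))


def _default_freqs(n_states: int, background: int) -> tuple[float, ...]:
    # roughly half the genome is quiescent in typical segmentations
    freqs = np.full(n_states, 0.5 / (n_states - 1))
    freqs[background] = 0.5
    return tuple(freqs)


def simulate_emissions(
    n_states: int = 18,
    n_marks: int = 6,
    concentration: float = 0.3,
    seed: int = 0,
    quiescent_last: bool = True,
) -> EmissionMatrix:
    """Random emission matrix with Dirichlet-distributed rows.

    Small ``concentration`` values give peaked, near-binary rows like
    real segmentation models; large values drive all rows towards
    uniform (and the derived scoring towards inapplicability, since all
    states become alike). With ``quiescent_last`` the final state's row
    is drawn near-uniform with low overall signal, mimicking the
    background state, and the alphabet declares it as such.
    """
    if n_states < 2:
        raise ValidationError("need at least two states")
    if concentration <= 0:
        raise ValidationError("Dirichlet concentration must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xE31]))
    probs = rng.dirichlet(np.full(n_marks, concentration), size=n_states)
    background = None
    if quiescent_last:
        background = n_states - 1
        quiet = rng.dirichlet(np.full(n_marks, 100.0))
        probs[background] = 0.05 * quiet / quiet.max()
    alphabet = StateAlphabet(
        tuple(f"E{i + 1}" for i in range(n_states)), background_state=background
    )
    marks = tuple(f"mark{j + 1}" for j in range(n_marks))
    return EmissionMatrix(alphabet, marks, probs)


def simulate_groups(config: SimConfig, emissions: EmissionMatrix) -> Dataset:
    """Simulate replicated group maps according to ``config``.

    Each group draws one i.i.d. template from the state frequencies;
    replicates copy the template and flip each bin with probability
    ``replicate_noise`` to a uniformly random *different* state. Planted
    domains overwrite their states afterwards, identically in every
    replicate of the respective group.
    """
    if emissions.alphabet.size != config.n_states:
        raise ValidationError("emissions do not match the configured state count")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0x5E6]))
    freqs = np.asarray(config.state_freqs)
    maps: list[SegmentationMap] = []
    groups: dict[str, SampleGroup] = {}
    for g_idx, (g_name, n_reps) in enumerate(zip(("X", "Y"), config.n_replicates)):
        template = {
            chrom: rng.choice(config.n_states, size=n_bins, p=freqs)
            for chrom, n_bins in sorted(config.chrom_lengths.items())
        }
        members = []
        for rep in range(n_reps):
            sample_id = f"{g_name}-{rep + 1}"
            chrom_states = {}
            for chrom, base in template.items():
                states = base.copy()
                if config.replicate_noise > 0:
                    flip = rng.random(states.size) < config.replicate_noise
                    n_flip = int(flip.sum())
                    if n_flip:
                        # uniform over the other n-1 states
                        offs = rng.integers(1, config.n_states, size=n_flip)
                        states[flip] = (states[flip] + offs) % config.n_states
                for dom in config.planted:
                    if dom.chrom == chrom:
                        states[dom.start:dom.end] = (
                            dom.state_x if g_idx == 0 else dom.state_y
                        )
                chrom_states[chrom] = states
            maps.append(SegmentationMap(sample_id, config.bin_size, chrom_states))
            members.append(sample_id)
        groups[g_name] = SampleGroup(g_name, tuple(members))
    return build_dataset(
        maps,
        emissions,
        groups,
        metadata={"simulated": True, "seed": int(config.seed)},
    )


def max_score_state_pair(matrix: ScoreMatrix) -> tuple[int, int]:
    """The (i, j) state pair with the highest dissimilarity score.

    Ties resolve to the lexicographically smallest pair; the background
    state never participates (its scores are the matrix minimum).
    """
    best = None
    for i in range(matrix.size):
        for j in range(matrix.size):
            if matrix.background_state in (i, j):
                continue
            s = int(matrix.scores[i, j])
            if best is None or s > best[0]:
                best = (s, i, j)
    if best is None or best[0] <= 0:
        raise ValidationError("score matrix has no positive non-background pair")
    return best[1], best[2]


def write_chromhmm_files(dataset: Dataset, out_dir) -> dict[str, str]:
    """Write the dataset back out as ChromHMM-style text files.

    Produces one 4-column segmentation BED per sample, an emissions TSV,
    a chromosome-sizes TSV and a sample-group table, so the simulator
    also exercises the real file-input path. Returns the written paths.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}
    bin_size = dataset.bin_size
    labels = dataset.alphabet.labels
    for sid, smap in sorted(dataset.maps.items()):
        path = os.path.join(out_dir, f"{sid}_segments.bed")
        with open(path, "w") as handle:
            for chrom in sorted(smap.chrom_states):
                vec = smap.chrom_states[chrom]
                change = np.flatnonzero(np.diff(vec)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [vec.size]))
                for a, b in zip(starts.tolist(), ends.tolist()):
                    handle.write(
                        f"{chrom}\t{a * bin_size}\t{b * bin_size}\t{labels[vec[a]]}\n"
                    )
        paths[sid] = path

    emis_path = os.path.join(out_dir, "emissions.tsv")
    with open(emis_path, "w") as handle:
        handle.write("State\t" + "\t".join(dataset.emissions.marks) + "\n")
        for i, lab in enumerate(labels):
            row = "\t".join(f"{v:.6f}" for v in dataset.emissions.probs[i])
            handle.write(f"{lab}\t{row}\n")
    paths["emissions"] = emis_path

    sizes_path = os.path.join(out_dir, "chrom.sizes")
    with open(sizes_path, "w") as handle:
        for chrom, n_bins in sorted(dataset.chrom_lengths.items()):
            handle.write(f"{chrom}\t{n_bins * bin_size}\n")
    paths["chrom_sizes"] = sizes_path

    groups_path = os.path.join(out_dir, "groups.tsv")
    with open(groups_path, "w") as handle:
        for name, group in sorted(dataset.groups.items()):
            for member in group.members:
                handle.write(f"{member}\t{name}\n")
    paths["groups"] = groups_path
    return paths
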