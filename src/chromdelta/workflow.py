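"""End-to-end comparison workflow.

Thin orchestration over the scoring, statistics, scan and merge modules:
derive (or accept) a scoring matrix, verify the applicability
assumptions, estimate lambda and K from the empirical group state
frequencies, scan all replicate pairs, merge candidates, assign E-values
and filter to the final DCD set. The result object carries everything a
report needs and serialises to a TSV table plus a JSON metadata sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from . import __version__
from .dataset import Dataset, SampleGroup
from .errors import ValidationError
from .karlin import KarlinParams, estimate_params
from .merge import (
    DEFAULT_E_THRESHOLD,
    EffectiveLength,
    MergedDomain,
    assign_evalues,
    comparison_length,
    effective_group_length,
    filter_dcds,
    merge_candidates,
)
from .scan import scan_comparison
from .scoring import (
    AssumptionReport,
    BackgroundFreqs,
    ScoreMatrix,
    build_score_matrix,
    check_assumptions,
    empirical_state_freqs,
)

__all__ = ["ComparisonResult", "run_comparison", "write_dcd_table"]


@dataclass(frozen=True)
class ComparisonResult:
    """Everything produced by one group-vs-group differential analysis."""

    group_x: SampleGroup
    group_y: SampleGroup
    matrix: ScoreMatrix
    report: AssumptionReport
    params: KarlinParams
    length: EffectiveLength
    domains: tuple[MergedDomain, ...]  # all merged candidates, E-annotated
    dcds: tuple[MergedDomain, ...]  # the E-filtered final set
    e_threshold: float
    bin_size: int

    @property
    def n_scans(self) -> int:
        return len(self.group_x.members) * len(self.group_y.members)

    def metadata(self) -> dict:
        return {
            "tool": "chromdelta",
            "version": __version__,
            "group_x": list(self.group_x.members),
            "group_y": list(self.group_y.members),
            "lambda": self.params.lam,
            "K": self.params.K,
            "score_range": list(self.params.score_range),
            "effective_length_bins": self.length.total,
            "e_threshold": self.e_threshold,
            "matrix_provenance": self.matrix.provenance,
            "bin_size": self.bin_size,
            "n_pairwise_scans": self.n_scans,
            "n_candidate_domains": len(self.domains),
            "n_dcds": len(self.dcds),
        }


def run_comparison(
    dataset: Dataset,
    group_x: SampleGroup | str,
    group_y: SampleGroup | str,
    matrix: ScoreMatrix | None = None,
    scale_factor: int | None = None,
    e_threshold: float = DEFAULT_E_THRESHOLD,
    length_rule: str = "max",
    mean_mode: str = "global",
) -> ComparisonResult:
    """Run the full differential analysis for one group pairing.

    Raises :class:`~chromdelta.errors.AssumptionError` when the scoring
    system fails the applicability checks under the empirical state
    frequencies of the two groups.
    """
    if isinstance(group_x, str):
        group_x = dataset.group(group_x)
    if isinstance(group_y, str):
        group_y = dataset.group(group_y)
    if set(group_x.members) & set(group_y.members):
        raise ValidationError("compared groups must be disjoint")

    if matrix is None:
        kwargs = {} if scale_factor is None else {"scale_factor": scale_factor}
        matrix = build_score_matrix(dataset.emissions, mean_mode=mean_mode, **kwargs)
    freqs = BackgroundFreqs(
        empirical_state_freqs(dataset, group_x),
        empirical_state_freqs(dataset, group_y),
    )
    report = check_assumptions(matrix, freqs)
    report.raise_if_failed()
    params = estimate_params(matrix, freqs)

    segments = scan_comparison(dataset, group_x, group_y, matrix)
    domains = merge_candidates(segments)
    length = comparison_length(
        effective_group_length(dataset.group_maps(group_x)),
        effective_group_length(dataset.group_maps(group_y)),
        rule=length_rule,
    )
    domains = assign_evalues(domains, params, length.total)
    dcds = filter_dcds(domains, e_threshold)
    return ComparisonResult(
        group_x=group_x,
        group_y=group_y,
        matrix=matrix,
        report=report,
        params=params,
        length=length,
        domains=tuple(domains),
        dcds=tuple(dcds),
        e_threshold=e_threshold,
        bin_size=dataset.bin_size,
    )


def write_dcd_table(result: ComparisonResult, path, sidecar: bool = True) -> None:
    """Write the DCD set as a BED-like TSV (bp coordinates) with header.

    With ``sidecar`` a ``<path>.meta.json`` file records lambda, K, L,
    matrix provenance and thresholds for reproducibility. Output is
    deterministic: identical results produce byte-identical files.
    """
    bs = result.bin_size
    with open(path, "w") as handle:
        handle.write(
            "chrom\tstart\tend\tdomain_id\tdcs\tevalue\tneg_log10_evalue"
            "\tn_support_pairs\tmember_pairs\n"
        )
        for idx, dom in enumerate(result.dcds):
            pairs = sorted({f"{x}:{y}" for x, y in (m.source_pair for m in dom.members)})
            handle.write(
                f"{dom.chrom}\t{dom.start * bs}\t{dom.end * bs}\t"
                f"DCD_{idx + 1:05d}\t{dom.dcs:.6g}\t{dom.evalue:.6e}\t"
                f"{dom.neg_log10_e:.6f}\t{dom.n_support_pairs}\t"
                f"{','.join(pairs)}\n"
            )
    if sidecar:
        with open(f"{path}.meta.json", "w") as handle:
            json.dump(result.metadata(), handle, indent=2, sort_keys=True)
            handle.write("\n")
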