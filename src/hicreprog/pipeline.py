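"""Stage-series orchestration: run the full analysis battery per stage.

A *stage* is one chromatin sample along a developmental trajectory (donor
cell, the two metaphase-like one-cell stages, and the post-activation
interphase stages through the ICM).  For each stage the pipeline balances
and depth-scales the matrix, computes the P(s) curve and chromatin-state
call, calls compartments and their segregation ratio, calls insulation
boundaries and TADs, and scores the relative TAD intensity of a common
reference TAD set (the most mature stage's TADs, by convention).  Cross-
stage tables collect these per stage so maturation trends are directly
comparable.

:func:`demo_scnt_trajectory` wires the synthetic generator to this battery
for a six-stage trajectory with the canonical narrative: an interphase donor
with strong TADs and compartments, a mitotic-metaphase stage (fall-off near
10 Mb), an MII-metaphase stage (fall-off near 4 Mb), and three interphase
stages with TAD strength and compartment plaid maturing back up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import compartments as cmp
from . import decay, domains, sim
from .contacts import ContactMatrix, ice_normalize, scale_to_depth

__all__ = ["StageResult", "PipelineReport", "run_pipeline", "demo_scnt_trajectory", "demo_stage_params"]


@dataclass
class StageResult:
    """Everything the battery computed for one stage."""

    label: str
    state: decay.StateCall
    ps_curve: decay.PsCurve
    profile: cmp.CompartmentProfile | None
    pc1_truth_corr: float | None
    segregation: float | None
    boundaries: domains.BoundarySet
    tads: pd.DataFrame
    rti: pd.DataFrame  # per reference TAD
    distance_classes: dict[str, float]
    iced: ContactMatrix


@dataclass
class PipelineReport:
    """Per-stage results plus cross-stage summary tables and a parameter log."""

    stages: list[StageResult]
    summary: pd.DataFrame
    rti_table: pd.DataFrame  # reference TADs x stages
    log: dict = field(default_factory=dict)

    def stage(self, label: str) -> StageResult:
        for s in self.stages:
            if s.label == label:
                return s
        raise KeyError(label)


def _analyze_stage(
    label: str,
    matrix: ContactMatrix,
    reference_tads: pd.DataFrame | None,
    orientation_track: np.ndarray | None,
    truth_compartments: np.ndarray | None,
    settings: dict,
) -> StageResult:
    iced = scale_to_depth(
        ice_normalize(matrix, filter_percentile=settings["filter_percentile"]),
        target=settings["scale_target"],
    )
    curve = decay.contact_probability(matrix, min_dist_bins=settings["min_dist_bins"])
    state = decay.classify_chromatin_state(curve)
    chrom = matrix.chromosomes[0]
    sub = iced.cis(chrom)

    profile = None
    pc1_corr = None
    segregation = None
    try:
        profile = cmp.compartment_pc1(sub, orientation_track=orientation_track)
        segregation = cmp.segregation_ratio(sub, profile)
        if truth_compartments is not None:
            both = profile.defined
            pc1_corr = float(
                abs(np.corrcoef(profile.pc1[both], truth_compartments[both])[0, 1])
            )
    except ValueError:
        pass

    ins = domains.insulation_score(
        sub,
        square_size=settings["insulation_square"],
        delta_span=settings["insulation_delta_span"],
        noise_threshold=settings["insulation_noise"],
    )
    boundaries = domains.call_boundaries(ins)
    tads = domains.tads_from_boundaries(boundaries)

    rti_rows = []
    if reference_tads is not None:
        for ti, tad in reference_tads.iterrows():
            try:
                r = domains.relative_tad_intensity(
                    sub, int(tad["start_bin"]), int(tad["end_bin"])
                )
            except ValueError:
                r = np.nan
            rti_rows.append((ti, tad["start_bin"], tad["end_bin"], r))
    rti = pd.DataFrame(rti_rows, columns=["tad_idx", "start_bin", "end_bin", "rti"])

    return StageResult(
        label=label,
        state=state,
        ps_curve=curve,
        profile=profile,
        pc1_truth_corr=pc1_corr,
        segregation=segregation,
        boundaries=boundaries,
        tads=tads,
        rti=rti,
        distance_classes=decay.distance_class_fractions(matrix),
        iced=iced,
    )


DEFAULT_SETTINGS = dict(
    filter_percentile=2.0,
    scale_target=1e8,
    min_dist_bins=2,
    insulation_square=1_000_000,
    insulation_delta_span=200_000,
    insulation_noise=0.25,
)


def run_pipeline(
    stages: list[tuple[str, ContactMatrix]],
    reference_tads: pd.DataFrame | None = None,
    orientation_track: np.ndarray | None = None,
    truth_compartments: np.ndarray | None = None,
    settings: dict | None = None,
) -> PipelineReport:
    """Run the per-stage battery and assemble cross-stage tables.

    ``stages`` is an ordered list of (label, raw ContactMatrix) sharing a
    bin table.  ``reference_tads`` (from :func:`domains.tads_from_boundaries`
    or planted truth) is scored for RTI at every stage; when omitted, the
    TADs called at the *last* stage serve as the reference, mirroring the
    use of the most mature stage's domains for all stages.  A stage whose
    battery step fails records NaN for that step and continues.
    """
    if not stages:
        raise ValueError("need at least one stage")
    labels = [lab for lab, _ in stages]
    if len(set(labels)) != len(labels):
        raise ValueError("stage labels must be unique")
    cfg = dict(DEFAULT_SETTINGS)
    if settings:
        cfg.update(settings)

    if reference_tads is None:
        last = stages[-1][1]
        iced = scale_to_depth(
            ice_normalize(last, filter_percentile=cfg["filter_percentile"]),
            target=cfg["scale_target"],
        )
        ins = domains.insulation_score(
            iced.cis(last.chromosomes[0]),
            square_size=cfg["insulation_square"],
            delta_span=cfg["insulation_delta_span"],
            noise_threshold=cfg["insulation_noise"],
        )
        reference_tads = domains.tads_from_boundaries(domains.call_boundaries(ins))
        reference_tads = reference_tads[
            reference_tads["end_bin"] - reference_tads["start_bin"] > 3
        ].reset_index(drop=True)

    results = [
        _analyze_stage(
            lab, mat, reference_tads, orientation_track, truth_compartments, cfg
        )
        for lab, mat in stages
    ]

    summary = pd.DataFrame(
        {
            "stage": [r.label for r in results],
            "state": [r.state.label for r in results],
            "exponent": [r.state.exponent for r in results],
            "falloff_bp": [r.state.falloff for r in results],
            "n_boundaries": [len(r.boundaries.table) for r in results],
            "segregation_ratio": [
                np.nan if r.segregation is None else r.segregation for r in results
            ],
            "pc1_truth_corr": [
                np.nan if r.pc1_truth_corr is None else r.pc1_truth_corr
                for r in results
            ],
            "mean_rti": [
                float(r.rti["rti"].dropna().mean()) if r.rti["rti"].notna().any() else np.nan
                for r in results
            ],
            "frac_lt_1Mb": [r.distance_classes["lt_1Mb"] for r in results],
            "frac_1_10Mb": [r.distance_classes["1_10Mb"] for r in results],
            "frac_gt_10Mb": [r.distance_classes["gt_10Mb"] for r in results],
        }
    )
    rti_table = pd.DataFrame(
        {r.label: r.rti.set_index("tad_idx")["rti"] for r in results}
    )
    return PipelineReport(stages=results, summary=summary, rti_table=rti_table, log=cfg)


def _demo_tads(n_bins: int) -> list[tuple[int, int]]:
    """Deterministic TAD partition used by the demo (sizes in bins)."""
    sizes = [12, 18, 10, 15, 20, 14, 16, 11, 19, 13, 17, 12, 15, 18, 10, 16, 14, 20]
    tads = []
    pos = 12  # leave the chromosome start outside any planted TAD
    k = 0
    while pos + sizes[k % len(sizes)] < n_bins - 12:
        sz = sizes[k % len(sizes)]
        tads.append((pos, pos + sz))
        pos += sz
        k += 1
    return tads


def demo_stage_params(
    seed: int = 0,
    n_bins: int = 500,
    bin_size: int = 100_000,
    depth: float = 2e6,
) -> list[sim.SimParams]:
    """The six demo stages: donor interphase, mitotic metaphase, MII
    metaphase, then a weak → intermediate → strong interphase ramp."""
    tads = _demo_tads(n_bins)
    comp = sim.alternating_compartments(n_bins, block=25)
    stage_defs = [
        # (alpha, d_c, beta, gamma, with_tads)
        (-1.0, None, 4.0, 0.50, True),   # donor cell: mature interphase
        (-0.5, 1e7, 0.0, 0.0, False),    # mitotic metaphase (~10 Mb fall-off)
        (-0.5, 4e6, 0.0, 0.0, False),    # MII metaphase (~4 Mb fall-off)
        (-1.0, None, 1.0, 0.25, True),   # weak re-establishment
        (-1.0, None, 2.0, 0.35, True),   # intermediate
        (-1.0, None, 4.0, 0.50, True),   # mature (ICM-like)
    ]
    specs = []
    for k, (alpha, d_c, beta, gamma, with_tads) in enumerate(stage_defs):
        specs.append(
            sim.SimParams(
                n_bins=n_bins,
                bin_size=bin_size,
                decay_exponent=alpha,
                cutoff_distance=d_c,
                tad_intervals=tuple((s, e, beta) for s, e in tads) if with_tads else (),
                compartment_vector=comp if gamma > 0 else None,
                plaid_strength=gamma,
                depth=depth,
                seed=seed,  # overridden per stage by simulate_stage_series
            )
        )
    return specs


DEMO_STAGE_LABELS = ["CC", "1hpi", "1hpa", "early", "mid", "ICM"]


def demo_scnt_trajectory(
    seed: int = 0,
    n_bins: int = 500,
    bin_size: int = 100_000,
    depth: float = 2e6,
) -> PipelineReport:
    """Synthetic six-stage trajectory run through the full battery.

    The report's summary table shows, per stage, the chromatin-state call
    (metaphase labels only at the two metaphase stages), boundary counts
    (zero at metaphase under the 0.25 noise threshold), compartment
    recovery, segregation ratio and mean RTI (both maturing across the
    post-activation stages).
    """
    specs = demo_stage_params(seed=seed, n_bins=n_bins, bin_size=bin_size, depth=depth)
    maps = sim.simulate_stage_series(specs, master_seed=seed)
    truth_ref = maps[0][1]  # donor-stage truth: planted TADs + compartments
    reference_tads = pd.DataFrame(
        [
            ("chr1", s * bin_size, e * bin_size, s, e)
            for s, e, _ in truth_ref.tad_intervals
        ],
        columns=["chrom", "start", "end", "start_bin", "end_bin"],
    )
    orientation = (truth_ref.compartment_vector > 0).astype(float)
    report = run_pipeline(
        stages=list(zip(DEMO_STAGE_LABELS, [m for m, _ in maps])),
        reference_tads=reference_tads,
        orientation_track=orientation,
        truth_compartments=truth_ref.compartment_vector.astype(float),
    )
    report.log["seed"] = seed
    report.log["n_bins"] = n_bins
    report.log["bin_size"] = bin_size
    report.log["depth"] = depth
    return report
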