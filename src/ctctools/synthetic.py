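"""Synthetic cohorts with the statistical structure the analysis assumes.

Every downstream stage of the package is testable without patient data:

* multi-group single-cell Ct matrices with group-specific ΔCt signatures,
  Ct-dependent dropout (high Ct — low expression — drops out more often) and
  a CD45-expressing white-blood-cell contrast group;
* per-patient CTC count trajectories linked to radiographic response, rising
  on average under progressive disease (default +70.1% per follow-up draw)
  and falling under partial response (default −43.1%), from 3 mL draws;
* right-censored Weibull survival times, optionally with a hazard ratio
  acting on the high-baseline-count arm above a true cutoff;
* paired tissue/CTC mutation call tables with a configurable expected
  sample-level concordance and optional emergent-resistance (T790M-like)
  BT -> AR pairs.

One global seed fans out to fixed, independent per-generator streams, so
calling one generator never perturbs another.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .emt import DEFAULT_EPITHELIAL, DEFAULT_MESENCHYMAL, MarkerPanel
from .kinetics import CTCTimeSeries, ResponseAssessment
from .matrix import SENTINEL, CT_VALID_MAX, CellAnnotation, CtMatrix
from .concordance import MutationCallTable
from .survival import SurvivalRecord

REFERENCE_GENE = "GAPDH"
LEUKOCYTE_MARKER = "PTPRC"  # CD45
WBC_GROUP = "WBC"

DEFAULT_GENES = (
    REFERENCE_GENE,
    *DEFAULT_EPITHELIAL,
    *DEFAULT_MESENCHYMAL,
    LEUKOCYTE_MARKER,
    "EGFR", "MET", "CDH1", "CDH2",
)

# Fixed spawn keys: one independent stream per generator.
_STREAMS = {"ct_matrix": 0, "trajectories": 1, "survival": 2, "mutations": 3,
            "emt_cells": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],))
    return np.random.default_rng(ss)


@dataclasses.dataclass
class SyntheticCohortConfig:
    """Stated world for the synthetic cohort.

    Defaults follow the study regime: 4 tumor-cell groups of ~20 cells plus a
    small WBC group; a 40-patient cohort whose PD arm gains +70.1% CTCs per
    follow-up draw (17 paired observations) while the PR arm loses 43.1%
    (24 observations); 3 mL draws with a 23-cell baseline (57.5 per 7.5 mL);
    baseline counts log-normal around a median of 37 per 7.5 mL; Weibull
    survival times on the order of the reported medians with half the
    records censored.
    """

    # single-cell matrix
    n_groups: int = 4
    cells_per_group: int = 20
    genes: tuple[str, ...] = DEFAULT_GENES
    group_delta_ct_means: Mapping[str, Mapping[str, float]] | None = None
    ct_noise_sd: float = 0.5            # cycles
    dropout_base_rate: float = 0.05
    dropout_ct_slope: float = 0.01      # added dropout probability per cycle
    low_quality_fraction: float = 0.05  # entries drawn below the 0.65 threshold
    include_wbc_group: bool = True
    wbc_cells: int = 5
    reference_ct: float = 20.0          # cycles
    # trajectories
    n_patients: int = 41
    arm_fractions: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"PD": 17 / 41, "PR": 24 / 41})
    response_effect: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"PD": 70.1, "PR": -43.1})
    trajectory_noise_sd: float = 35.0   # percent, per follow-up draw
    baseline_count: int = 23            # raw cells per 3 mL draw
    draw_volume_ml: float = 3.0
    draw_days: tuple[int, ...] = (0, 63, 126)
    scan_days: tuple[int, ...] = (57, 120)
    # survival
    survival_shape: float = 1.3
    survival_scale: float = 700.0       # days
    censoring_rate: float = 0.5
    baseline_count_median_75: float = 37.0
    baseline_count_log_sigma: float = 0.7
    # mutations
    concordance_target: float = 1.0
    n_mutation_samples: int = 15
    seed: int = 0

    def validate(self) -> None:
        for name in ("dropout_base_rate", "low_quality_fraction",
                     "censoring_rate", "concordance_target"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_groups", "cells_per_group", "n_patients",
                     "n_mutation_samples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")
        if self.dropout_ct_slope < 0:
            raise ValueError("dropout_ct_slope must be >= 0")
        if self.survival_shape <= 0 or self.survival_scale <= 0:
            raise ValueError("survival shape and scale must be positive")
        if REFERENCE_GENE not in self.genes:
            raise ValueError(f"reference gene {REFERENCE_GENE!r} missing from genes")
        if abs(sum(self.arm_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("arm_fractions must sum to 1")
        if self.draw_days[0] != 0:
            raise ValueError("first draw day must be 0 (baseline)")


def default_group_means(
    genes: Sequence[str], n_groups: int, separation: float = 4.0,
    low: float = 6.0,
) -> dict[str, dict[str, float]]:
    """Block-structured ΔCt signatures: each group strongly expresses its own
    round-robin slice of the non-reference genes (ΔCt ``low``), everything
    else sits ``separation`` cycles higher.  The WBC group expresses only the
    leukocyte marker and has near-zero epithelial expression (very high ΔCt).
    """
    high = low + separation
    targets = [g for g in genes if g != REFERENCE_GENE]
    means: dict[str, dict[str, float]] = {}
    for g in range(n_groups):
        name = f"G{g + 1}"
        means[name] = {}
        for j, gene in enumerate(targets):
            means[name][gene] = low if j % n_groups == g else high
        means[name][LEUKOCYTE_MARKER] = 16.0  # tumor cells: no CD45
    wbc = {gene: 12.0 for gene in targets}
    for gene in DEFAULT_EPITHELIAL:
        if gene in wbc:
            wbc[gene] = 16.0
    wbc[LEUKOCYTE_MARKER] = 4.0
    means[WBC_GROUP] = wbc
    return means


def generate_ct_matrix(
    config: SyntheticCohortConfig,
) -> tuple[CtMatrix, pd.Series]:
    """Draw a genes x cells Ct matrix plus the true group labels.

    Ct(g, c) = reference Ct(c) + group ΔCt mean(g) + N(0, ct_noise_sd), with
    entries dropped to the 999 sentinel with probability
    clip(dropout_base_rate + dropout_ct_slope * (Ct − min Ct), 0, 1).
    """
    config.validate()
    rng = _rng(config.seed, "ct_matrix")
    means = config.group_delta_ct_means
    if means is None:
        means = default_group_means(config.genes, config.n_groups)
    groups = [f"G{g + 1}" for g in range(config.n_groups)]
    sizes = {g: config.cells_per_group for g in groups}
    if config.include_wbc_group and WBC_GROUP in means:
        groups.append(WBC_GROUP)
        sizes[WBC_GROUP] = config.wbc_cells
    genes = list(config.genes)
    columns, labels, cols = [], [], []
    annotations = {}
    for group in groups:
        gmeans = means[group]
        for i in range(sizes[group]):
            cell_id = f"{group}_c{i + 1}"
            ct = np.empty(len(genes))
            for j, gene in enumerate(genes):
                # each well carries independent noise of exactly ct_noise_sd
                mean = (config.reference_ct if gene == REFERENCE_GENE
                        else config.reference_ct + float(gmeans[gene]))
                ct[j] = mean + rng.normal(0.0, config.ct_noise_sd)
            cols.append(np.clip(ct, 0.1, CT_VALID_MAX))
            columns.append(cell_id)
            labels.append(group)
            annotations[cell_id] = CellAnnotation(
                cell_id=cell_id, source_group=group,
                cd45=(group == WBC_GROUP),
                ck_epcam=(group != WBC_GROUP), dapi=True,
            )
    ct = pd.DataFrame(np.column_stack(cols), index=genes, columns=columns)
    # Ct-dependent dropout: weakly expressed (high-Ct) genes fail more often.
    arr = ct.to_numpy()
    p_drop = np.clip(
        config.dropout_base_rate
        + config.dropout_ct_slope * (arr - arr.min()), 0.0, 1.0,
    )
    dropped = rng.random(arr.shape) < p_drop
    arr[dropped] = SENTINEL
    # quality scores: a configurable fraction below the 0.65 threshold
    low = rng.random(arr.shape) < config.low_quality_fraction
    quality = np.where(low, rng.uniform(0.0, 0.65, arr.shape),
                       rng.uniform(0.65, 1.0, arr.shape))
    m = CtMatrix(pd.DataFrame(arr, index=genes, columns=columns),
                 pd.DataFrame(quality, index=genes, columns=columns),
                 annotations)
    return m, pd.Series(labels, index=columns, name="group")


def generate_emt_cells(
    k: float,
    n_cells: int = 50,
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    panel: MarkerPanel | None = None,
    epithelial_delta_ct: float = 5.0,
) -> CtMatrix:
    """Cells whose mesenchymal expression sum is exactly k x the epithelial sum.

    In the noise-free limit the M-score of every cell is 100*k/(1+k); with
    Gaussian Ct noise the construction holds in expectation of the group.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    panel = panel or MarkerPanel()
    rng = _rng(seed, "emt_cells")
    n_e, n_m = len(panel.epithelial), len(panel.mesenchymal)
    a = epithelial_delta_ct
    # m_sum = n_m * 2^-b = k * n_e * 2^-a  =>  b = a - log2(k * n_e / n_m)
    b = a - math.log2(k * n_e / n_m)
    genes = [panel.reference_gene, *panel.epithelial, *panel.mesenchymal]
    ref_ct = 20.0
    cols = {}
    for i in range(n_cells):
        ct = {panel.reference_gene: ref_ct}
        for gene in panel.epithelial:
            ct[gene] = ref_ct + a + rng.normal(0.0, ct_noise_sd)
        for gene in panel.mesenchymal:
            ct[gene] = ref_ct + b + rng.normal(0.0, ct_noise_sd)
        cols[f"emt_c{i + 1}"] = [ct[g] for g in genes]
    return CtMatrix(pd.DataFrame(cols, index=genes))


def generate_ctc_trajectories(
    config: SyntheticCohortConfig,
) -> list[tuple[CTCTimeSeries, list[ResponseAssessment]]]:
    """Response-linked count trajectories from 3 mL draws.

    Every patient has a baseline draw at day 0 with ``baseline_count`` cells;
    each follow-up draw realizes a per-draw percent change of
    ``response_effect[arm] + N(0, trajectory_noise_sd)`` as a Poisson count
    (so raw counts are non-negative integers).  With
    ``trajectory_noise_sd=0`` the exact expected counts are returned instead,
    so arm means equal the configured effects exactly.  RECIST labels carry
    the arm's category at every scan day.
    """
    config.validate()
    rng = _rng(config.seed, "trajectories")
    arms: list[str] = []
    remaining = config.n_patients
    items = list(config.arm_fractions.items())
    for arm, frac in items[:-1]:
        k = round(config.n_patients * frac)
        arms += [arm] * k
        remaining -= k
    arms += [items[-1][0]] * remaining
    out = []
    noisy = config.trajectory_noise_sd > 0
    for p, arm in enumerate(arms):
        pid = f"SP{p + 1:03d}"
        effect = float(config.response_effect[arm])
        counts = [(0, float(config.baseline_count), config.draw_volume_ml)]
        for day in config.draw_days[1:]:
            delta = effect
            if noisy:
                delta = effect + rng.normal(0.0, config.trajectory_noise_sd)
            lam = max(0.0, config.baseline_count * (1.0 + delta / 100.0))
            count = float(rng.poisson(lam)) if noisy else lam
            counts.append((day, count, config.draw_volume_ml))
        series = CTCTimeSeries.from_counts(pid, counts)
        assessments = [ResponseAssessment(pid, day, arm)
                       for day in config.scan_days]
        out.append((series, assessments))
    return out


def generate_survival_cohort(
    config: SyntheticCohortConfig,
    true_cutoff: float | None = None,
    hazard_ratio: float = 1.0,
    endpoint: str = "OS",
) -> list[SurvivalRecord]:
    """Right-censored Weibull survival times with baseline CTC counts.

    Times are Weibull(shape, scale); with ``hazard_ratio != 1`` the arm with
    baseline counts above ``true_cutoff`` has its times scaled by
    HR^(−1/shape) (proportional hazards).  Each record is independently
    censored with probability ``censoring_rate`` at a uniform fraction of
    its event time.
    """
    config.validate()
    rng = _rng(config.seed, "survival")
    n = config.n_patients
    mu = math.log(config.baseline_count_median_75)
    counts = rng.lognormal(mean=mu, sigma=config.baseline_count_log_sigma, size=n)
    times = config.survival_scale * rng.weibull(config.survival_shape, size=n)
    if true_cutoff is not None and hazard_ratio != 1.0:
        high = counts > true_cutoff
        times[high] *= hazard_ratio ** (-1.0 / config.survival_shape)
    censored = rng.random(n) < config.censoring_rate
    obs_times = np.where(censored, times * rng.uniform(0.0, 1.0, size=n), times)
    obs_times = np.maximum(obs_times, 1e-3)
    return [
        SurvivalRecord(
            patient_id=f"SP{i + 1:03d}",
            time=float(obs_times[i]),
            event=int(not censored[i]),
            endpoint=endpoint,
            baseline_count_75=float(counts[i]),
        )
        for i in range(n)
    ]


def generate_mutation_table(
    config: SyntheticCohortConfig,
    n_samples: int | None = None,
    n_emergent_pairs: int = 0,
    t790m_rate: float = 0.15,
) -> MutationCallTable:
    """Paired tissue/CTC calls with a configured expected concordance.

    Tissue calls: activating locus always positive, T790M positive at
    ``t790m_rate``.  CTC calls copy the tissue calls, then each locus flips
    independently with probability 1 − concordance_target^(1/L), so the
    expected all-loci sample concordance is exactly ``concordance_target``.
    ``n_emergent_pairs`` patients additionally contribute BT/AR sample pairs
    whose T790M flips − to + in both tissue and CTC at relapse (concordant).
    """
    config.validate()
    rng = _rng(config.seed, "mutations")
    n = n_samples if n_samples is not None else config.n_mutation_samples
    n_loci = 2
    flip_p = 1.0 - config.concordance_target ** (1.0 / n_loci)
    rows = []
    for i in range(n):
        pid = f"SM{i + 1:04d}"
        activating = "L858R" if rng.random() < 0.5 else "19del"
        tissue = {activating: "+",
                  "T790M": "+" if rng.random() < t790m_rate else "-"}
        for locus, t_call in tissue.items():
            c_call = t_call
            if rng.random() < flip_p:
                c_call = "+" if t_call == "-" else "-"
            rows.append((pid, pid, "", locus, t_call, c_call))
    for j in range(n_emergent_pairs):
        pid = f"SE{j + 1:04d}"
        activating = "L858R" if rng.random() < 0.5 else "19del"
        for stage, t790m in (("BT", "-"), ("AR", "+")):
            rows.append((f"{pid}-{stage}", pid, stage, activating, "+", "+"))
            rows.append((f"{pid}-{stage}", pid, stage, "T790M", t790m, t790m))
    df = pd.DataFrame(rows, columns=["sample_id", "patient_id", "stage",
                                     "locus", "tissue_call", "ctc_call"])
    return MutationCallTable(df)
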