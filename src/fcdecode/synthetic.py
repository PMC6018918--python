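"""Synthetic cohort, parcellation, expression and gene-table generators.

Every downstream stage of the pipeline is exercised on data produced here:
two-group BOLD cohorts with a planted inter-regional over-connectivity effect,
block parcellations, expression-energy matrices with planted high-expression
gene sets in a chosen region pair, and differential-expression / risk-gene
tables realizing exact overlap counts. All generators are pure functions of
their configuration including the seed.

The connectivity effect is planted through a shared latent signal: voxels of
the two planted regions receive ``sqrt(rho) * latent + sqrt(1 - rho) * private``
where latent and private components are AR(1) processes with identical
stationary variance, so the expected pairwise correlation between any two
planted voxels equals ``rho`` by construction. Temporal noise is AR(1)
(default coefficient 0.3), the minimal temporally correlated model. Nuisance
structure comprises a slow ventricular confound carried by a dedicated
ventricle block (and bleeding weakly into brain voxels) and six motion traces
built as smoothed random walks that couple into the signal with small random
voxelwise loadings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from fcdecode.types import BoldSeries, NuisanceSet, Parcellation

#: fraction of the ventricular confound that bleeds into brain voxels
_VENT_BLEED = 0.2
#: amplitude of the motion-coupled signal component relative to nuisance_amplitude
_MOTION_COUPLING = 0.1
#: mean baseline offset of the raw BOLD signal (arbitrary units)
_BASELINE = 100.0


@dataclass
class CohortConfig:
    """Study conditions for a two-group synthetic BOLD cohort.

    Defaults are a scaled-down version of a 23 + 19 mouse cohort acquired at
    TR 1.2 s with 500 volumes: 6 + 6 subjects on a 20 x 20 x 4 grid with 220
    timepoints, so 200 remain after trimming the first 20 volumes.
    """

    n_group_a: int = 6
    n_group_b: int = 6
    grid_shape: tuple[int, int, int] = (20, 20, 4)
    n_timepoints: int = 220
    tr_seconds: float = 1.2
    ar1_coeff: float = 0.3
    n_regions: int = 12
    planted_pair: tuple[int, int] = (3, 8)
    planted_corr_a: float = 0.0
    planted_corr_b: float = 0.0
    nuisance_amplitude: float = 0.5
    # 20 x 20 in-plane voxels spanning the acquisition's 2 x 2 cm field of
    # view, 4 slices spanning the 12 mm slice stack: coarse voxels are the
    # physically consistent counterpart of the scaled-down grid
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 3.0)
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_group_a < 1 or self.n_group_b < 1:
            raise ValueError("both groups need at least one subject")
        if len(self.grid_shape) != 3 or any(int(s) <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be >= 2")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not 0 <= self.ar1_coeff < 1:
            raise ValueError("ar1_coeff must lie in [0, 1)")
        for rho in (self.planted_corr_a, self.planted_corr_b):
            if not -1 < rho < 1:
                raise ValueError("planted correlations must lie in (-1, 1)")
        if self.nuisance_amplitude < 0:
            raise ValueError("nuisance_amplitude must be nonnegative")
        if self.planted_pair[0] == self.planted_pair[1]:
            raise ValueError("planted_pair must name two distinct regions")


@dataclass
class SyntheticSubject:
    """One simulated subject: BOLD series, nuisance regressors, group label."""

    subject_id: str
    group: str
    series: BoldSeries
    nuisance: NuisanceSet


@dataclass
class SyntheticCohort:
    """Full simulated cohort plus the shared anatomy it was generated on."""

    subjects: list[SyntheticSubject]
    parcellation: Parcellation
    ventricle_mask: np.ndarray
    config: CohortConfig = field(repr=False, default=None)  # type: ignore[assignment]

    def group(self, label: str) -> list[SyntheticSubject]:
        return [s for s in self.subjects if s.group == label]


@dataclass
class PlantedExpressionConfig:
    """Conditions for a synthetic genes x regions expression-energy matrix."""

    n_genes: int = 500
    n_regions: int = 40
    focal_pair: tuple[int, int] = (3, 8)
    enriched_set_size: int = 50
    enrichment_effect: float = 5.0
    n_decoy_sets: int = 9
    baseline_sigma: float = 0.5
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 2 or self.n_regions < 2:
            raise ValueError("need at least 2 genes and 2 regions")
        if not 0 < self.enriched_set_size < self.n_genes:
            raise ValueError("enriched_set_size must be in (0, n_genes)")
        if self.enrichment_effect <= 0:
            raise ValueError("enrichment_effect must be positive")
        r1, r2 = self.focal_pair
        if r1 == r2 or not (0 <= r1 < self.n_regions and 0 <= r2 < self.n_regions):
            raise ValueError("focal_pair must be two distinct region indices < n_regions")


def generate_parcellation(
    grid_shape: tuple[int, int, int], n_regions: int, rng_seed: int = 0
) -> Parcellation:
    """Partition a voxel grid into ``n_regions`` connected rectangular blocks.

    Labels run 1..n_regions; every region covers at least one voxel. The
    partition is built by recursive proportional bisection of the bounding
    box along its longest axis, which guarantees face-connected regions.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    n_vox = int(np.prod(grid_shape))
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    if n_regions > n_vox:
        raise ValueError(f"cannot fit {n_regions} regions into {n_vox} voxels")

    labels = np.zeros(grid_shape, dtype=np.int32)
    # stack of (slice triple, number of regions to place inside)
    stack: list[tuple[tuple[slice, slice, slice], int]] = [
        ((slice(0, grid_shape[0]), slice(0, grid_shape[1]), slice(0, grid_shape[2])), n_regions)
    ]
    blocks: list[tuple[slice, slice, slice]] = []
    while stack:
        box, k = stack.pop()
        if k == 1:
            blocks.append(box)
            continue
        sizes = [s.stop - s.start for s in box]
        k1 = k // 2
        k2 = k - k1
        # split along the longest axis that can hold both sub-counts
        for axis in sorted(range(3), key=lambda a: -sizes[a]):
            length = sizes[axis]
            other = sizes[:axis] + sizes[axis + 1 :]
            plane = int(np.prod(other))
            cut = max(1, round(length * k1 / k))
            cut = min(cut, length - 1)
            # each side must be able to host its region count
            while cut * plane < k1 and cut < length - 1:
                cut += 1
            while (length - cut) * plane < k2 and cut > 1:
                cut -= 1
            if cut * plane >= k1 and (length - cut) * plane >= k2:
                s = box[axis]
                left = box[:axis] + (slice(s.start, s.start + cut),) + box[axis + 1 :]
                right = box[:axis] + (slice(s.start + cut, s.stop),) + box[axis + 1 :]
                stack.append((left, k1))
                stack.append((right, k2))
                break
        else:  # pragma: no cover - proportional cuts always admit a split
            raise ValueError("could not split box; infeasible region count")

    order = np.random.default_rng(rng_seed).permutation(len(blocks))
    for lab, idx in enumerate(order, start=1):
        labels[blocks[idx]] = lab
    return Parcellation(labels=labels)


def _ar1(rng: np.random.Generator, shape: tuple[int, ...], phi: float) -> np.ndarray:
    """Stationary unit-variance AR(1) series along the last axis."""
    eps = rng.standard_normal(shape)
    if phi == 0:
        return eps
    x0 = rng.standard_normal(shape[:-1])
    # x_t = phi^t x_0 + sqrt(1-phi^2) sum_{j<t} phi^j e_{t-j}: exactly stationary
    innov = eps * np.sqrt(1.0 - phi**2)
    innov[..., 0] = 0.0
    out = sps.lfilter([1.0], [1.0, -phi], innov, axis=-1)
    decay = phi ** np.arange(shape[-1])
    return out + x0[..., None] * decay


def _smoothed_walk(rng: np.random.Generator, n: int, n_cols: int, scale: float) -> np.ndarray:
    """Smoothed random walks emulating slowly drifting motion parameters."""
    steps = rng.standard_normal((n, n_cols)) * scale
    walk = np.cumsum(steps, axis=0)
    kernel = np.hanning(11)
    kernel /= kernel.sum()
    return np.apply_along_axis(lambda c: np.convolve(c, kernel, mode="same"), 0, walk)


def _carve_ventricle(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Small block in the grid's first corner reserved for the ventricle."""
    nx, ny, nz = grid_shape
    vent = np.zeros(grid_shape, dtype=bool)
    vent[: max(1, min(2, nx)), : max(1, min(2, ny)), : max(1, nz // 2 or 1)] = True
    return vent


def cohort_anatomy(config: CohortConfig) -> tuple[Parcellation, np.ndarray, np.ndarray]:
    """Shared anatomy for a cohort: parcellation, ventricle mask, brain mask.

    The ventricle occupies a reserved corner block (label 0 in the
    parcellation); the remaining voxels are parcellated into connected
    blocks. The brain mask covers the whole grid.
    """
    nx, ny, nz = (int(s) for s in config.grid_shape)
    vent = _carve_ventricle((nx, ny, nz))
    vx = 2 if nx > 2 else 1
    sub = generate_parcellation((nx - vx, ny, nz), config.n_regions, config.rng_seed)
    labels = np.zeros((nx, ny, nz), dtype=np.int32)
    labels[vx:, :, :] = sub.labels
    parc = Parcellation(labels=labels)
    brain = np.ones((nx, ny, nz), dtype=bool)
    for lab in config.planted_pair:
        if lab not in parc.region_labels:
            raise ValueError(f"planted region label {lab} missing from parcellation")
    return parc, vent, brain


def generate_bold_cohort(config: CohortConfig) -> SyntheticCohort:
    """Simulate a two-group BOLD cohort with a planted connectivity effect.

    Each subject's voxel time series is a stationary AR(1) process; voxels in
    the two planted regions additionally share a latent AR(1) signal mixed so
    their expected pairwise correlation equals the group's planted value. The
    ventricle block carries a slow confound at ``nuisance_amplitude``, which
    also bleeds weakly into brain voxels; motion traces couple into the data
    through small random voxel loadings. Identical seeds give bit-identical
    cohorts.
    """
    config.validate()
    parc, vent, brain = cohort_anatomy(config)
    rng = np.random.default_rng(config.rng_seed)
    t = config.n_timepoints
    phi = config.ar1_coeff

    r1_mask = parc.labels == config.planted_pair[0]
    r2_mask = parc.labels == config.planted_pair[1]
    planted_mask = r1_mask | r2_mask
    n_planted = int(planted_mask.sum())
    n_vox = int(np.prod(config.grid_shape))

    subjects: list[SyntheticSubject] = []
    groups = [("a", config.n_group_a, config.planted_corr_a), (
        "b",
        config.n_group_b,
        config.planted_corr_b,
    )]
    for group, n_subj, rho in groups:
        for i in range(n_subj):
            noise = _ar1(rng, (n_vox, t), phi)
            data = noise.reshape(config.grid_shape + (t,))
            if rho != 0.0:
                latent = _ar1(rng, (t,), phi)
                w = np.sqrt(abs(rho))
                mix = np.sqrt(1.0 - abs(rho))
                sgn = np.where(r2_mask[planted_mask], np.sign(rho), 1.0)
                data[planted_mask] = (
                    sgn[:, None] * w * latent[None, :]
                    + mix * data[planted_mask]
                )
            else:
                _ = _ar1(rng, (t,), phi)  # keep the stream layout group-independent

            # ventricular confound: slow drift, strongest inside the ventricle
            vent_sig = _ar1(rng, (t,), 0.95)
            amp = config.nuisance_amplitude
            data[vent] += amp * vent_sig[None, :]
            data[brain & ~vent] += _VENT_BLEED * amp * vent_sig[None, :]

            motion = _smoothed_walk(rng, t, 6, scale=0.02)
            loadings = rng.standard_normal((n_vox, 6)) * _MOTION_COUPLING * amp
            data += (loadings @ motion.T).reshape(config.grid_shape + (t,))
            data += _BASELINE

            series = BoldSeries(
                data=data,
                voxel_size_mm=config.voxel_size_mm,
                tr_seconds=config.tr_seconds,
                brain_mask=brain,
            )
            vent_course = data[vent].mean(axis=0)
            nuis = NuisanceSet(ventricular_signal=vent_course, motion_traces=motion)
            subjects.append(
                SyntheticSubject(
                    subject_id=f"sub-{group}{i:02d}", group=group, series=series, nuisance=nuis
                )
            )
    return SyntheticCohort(
        subjects=subjects, parcellation=parc, ventricle_mask=vent, config=config
    )


def planted_pair_correlation(cohort: SyntheticCohort, group: str) -> float:
    """Mean pairwise voxel correlation between the two planted regions.

    Direct sample-correlation readout used to calibrate the planted effect:
    averages Pearson r over all cross-region voxel pairs and subjects.
    """
    cfg = cohort.config
    r1 = cohort.parcellation.labels == cfg.planted_pair[0]
    r2 = cohort.parcellation.labels == cfg.planted_pair[1]
    vals = []
    for subj in cohort.group(group):
        x = subj.series.data[r1]
        y = subj.series.data[r2]
        x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        y = (y - y.mean(axis=1, keepdims=True)) / y.std(axis=1, keepdims=True)
        vals.append((x @ y.T).mean() / x.shape[1])
    return float(np.mean(vals))


def generate_expression_matrix(config: PlantedExpressionConfig):
    """Synthetic genes x regions expression energies with a planted enriched set.

    Baseline energies are lognormal around 1; genes of the planted set are
    boosted multiplicatively by ``enrichment_effect`` in both focal regions.
    Returns the raw (un-normalized) matrix and a gene-set annotation mapping
    containing the planted set plus random decoy sets of the same size.
    Deferred import avoids a module cycle with :mod:`fcdecode.decoding`.
    """
    from fcdecode.decoding import ExpressionMatrix

    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    regions = [f"R{j:03d}" for j in range(config.n_regions)]
    energies = rng.lognormal(mean=0.0, sigma=config.baseline_sigma,
                             size=(config.n_genes, config.n_regions))
    planted_idx = rng.choice(config.n_genes, size=config.enriched_set_size, replace=False)
    r1, r2 = config.focal_pair
    energies[np.ix_(planted_idx, [r1, r2])] *= config.enrichment_effect

    annotations: dict[str, list[str]] = {
        "planted_set": sorted(genes[i] for i in planted_idx)
    }
    for d in range(config.n_decoy_sets):
        decoy = rng.choice(config.n_genes, size=config.enriched_set_size, replace=False)
        annotations[f"decoy_set_{d:02d}"] = sorted(genes[i] for i in decoy)

    matrix = ExpressionMatrix(
        gene_ids=genes, region_labels=regions, energies=energies, normalized=False
    )
    return matrix, annotations


def generate_deg_table(
    n_universe: int,
    n_deg: int,
    risk_list_size: int,
    overlap: int,
    rng_seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Differential-expression table and risk-gene list with exact overlap.

    Constructs a gene universe, marks ``n_deg`` genes as differentially
    expressed (adjusted p < 0.05) and draws a risk list of ``risk_list_size``
    genes of which exactly ``overlap`` are differentially expressed, so the
    2x2 contingency rebuilt from the outputs equals the requested counts.
    """
    if overlap > min(n_deg, risk_list_size):
        raise ValueError("overlap exceeds one of the set sizes")
    if max(n_deg, risk_list_size) > n_universe:
        raise ValueError("set sizes exceed the universe")
    rng = np.random.default_rng(rng_seed)
    genes = np.array([f"G{i:05d}" for i in range(n_universe)])
    perm = rng.permutation(n_universe)
    deg_idx = perm[:n_deg]
    nondeg_idx = perm[n_deg:]
    risk_idx = np.concatenate(
        [
            rng.choice(deg_idx, size=overlap, replace=False),
            rng.choice(nondeg_idx, size=risk_list_size - overlap, replace=False),
        ]
    )

    is_deg = np.zeros(n_universe, dtype=bool)
    is_deg[deg_idx] = True
    log2fc = np.where(is_deg, rng.normal(0, 2, n_universe), rng.normal(0, 0.2, n_universe))
    pvalue = np.where(is_deg, rng.uniform(1e-10, 1e-4, n_universe), rng.uniform(0.1, 1, n_universe))
    padj = np.where(is_deg, pvalue * 50, np.minimum(1.0, pvalue * 1.5))
    table = pd.DataFrame(
        {"gene_id": genes, "log2fc": log2fc, "pvalue": pvalue, "padj": padj}
    )
    risk_list = sorted(genes[risk_idx].tolist())
    return table, risk_list
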