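"""Single-image ERP analysis: regression, AIC, SNR, electrode RDMs.

An ERP dataset holds stimulus-locked average responses per subject, image,
electrode and timepoint.  Image statistics are tested as linear predictors
of ERP amplitude independently at every (subject, electrode, timepoint);
candidate statistic sets are compared with AIC and unique-variance
partitioning.  Multi-electrode response patterns yield time-resolved
256x256 representational dissimilarity matrices (Euclidean distance),
which are correlated with statistic-space distance matrices by Mantel
permutation tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .similarity import MantelResult, _check_distance_matrix

DEFAULT_SAMPLING_RATE = 256.0  # Hz
DEFAULT_EPOCH_MS = (-100.0, 500.0)


@dataclass
class ERPDataset:
    """amplitude[subject, image, electrode, timepoint] plus axis metadata."""

    amplitude: np.ndarray
    electrode_names: list
    times_ms: np.ndarray
    subject_ids: list = field(default_factory=list)
    sampling_rate: float = DEFAULT_SAMPLING_RATE

    def __post_init__(self) -> None:
        s, i, e, t = self.amplitude.shape
        if len(self.electrode_names) != e:
            raise ValueError("electrode_names length mismatch")
        if len(self.times_ms) != t:
            raise ValueError("times_ms length mismatch")
        if len(set(self.electrode_names)) != e:
            raise ValueError("electrode names must be unique")
        if not self.subject_ids:
            self.subject_ids = [f"S{k + 1:02d}" for k in range(s)]

    @property
    def n_subjects(self) -> int:
        return self.amplitude.shape[0]

    @property
    def n_images(self) -> int:
        return self.amplitude.shape[1]

    def electrode_index(self, names: Sequence[str]) -> np.ndarray:
        lookup = {n: k for k, n in enumerate(self.electrode_names)}
        return np.array([lookup[n] for n in names])

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("amplitude", data=self.amplitude)
            f.create_dataset("time_ms", data=self.times_ms)
            f.create_dataset(
                "electrode_names",
                data=np.array(self.electrode_names, dtype="S"),
            )
            f.create_dataset("subject_ids", data=np.array(self.subject_ids, dtype="S"))
            f.attrs["sampling_rate"] = self.sampling_rate

    @classmethod
    def from_hdf5(cls, path) -> "ERPDataset":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                amplitude=f["amplitude"][()],
                electrode_names=[s.decode() for s in f["electrode_names"][()]],
                times_ms=f["time_ms"][()],
                subject_ids=[s.decode() for s in f["subject_ids"][()]],
                sampling_rate=float(f.attrs["sampling_rate"]),
            )


@dataclass
class RegressionResult:
    r_squared: np.ndarray  # (S, E, T)
    coefficients: np.ndarray  # (S, E, T, k + 1) incl. intercept first
    rss: np.ndarray  # (S, E, T)
    p_values: np.ndarray  # (S, E, T) overall F-test p
    n: int
    k: int


def regress_erp(dataset: ERPDataset, predictors: np.ndarray) -> RegressionResult:
    """OLS of ERP amplitude on image statistics, per (subject, electrode, t).

    ``predictors`` is an (n_images, k) matrix aligned with the image axis;
    an intercept is always included.  All regressions are solved in one
    pass through the pseudoinverse of the shared design matrix.
    """
    x = np.asarray(predictors, dtype=np.float64)
    if x.ndim == 1:
        x = x[:, None]
    n, k = x.shape
    if n != dataset.n_images:
        raise ValueError("predictor rows must align with the image axis")
    design = np.column_stack([np.ones(n), x])
    rank = np.linalg.matrix_rank(design)
    if rank < k + 1:
        corr = np.corrcoef(x, rowvar=False)
        raise ValueError(
            f"rank-deficient predictors (rank {rank} < {k + 1}); "
            f"correlation matrix:\n{np.round(np.atleast_2d(corr), 4)}"
        )

    s, _, e, t = dataset.amplitude.shape
    y = dataset.amplitude.transpose(1, 0, 2, 3).reshape(n, -1)
    coef = np.linalg.pinv(design) @ y  # (k+1, S*E*T)
    resid = y - design @ coef
    rss = (resid**2).sum(axis=0)
    tss = ((y - y.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(tss > 0, 1.0 - rss / tss, 0.0)
    r2 = np.clip(r2, 0.0, 1.0)

    dfn, dfd = k, n - k - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = np.where(r2 < 1.0, (r2 / dfn) / ((1 - r2) / dfd), np.inf)
    p = stats.f.sf(f_stat, dfn, dfd)

    shape = (s, e, t)
    return RegressionResult(
        r_squared=r2.reshape(shape),
        coefficients=coef.T.reshape(shape + (k + 1,)),
        rss=rss.reshape(shape),
        p_values=p.reshape(shape),
        n=n,
        k=k,
    )


def aic_from_rss(rss: np.ndarray | float, n: int, k: int) -> np.ndarray | float:
    """AIC = n·log(RSS/n) + 2k (natural log); -inf where RSS = 0."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rss = np.asarray(rss, dtype=np.float64)
    out = np.full_like(rss, -np.inf)
    pos = rss > 0
    if not pos.all():
        import warnings

        warnings.warn("RSS = 0 encountered; AIC set to -inf", RuntimeWarning)
    out[pos] = n * np.log(rss[pos] / n) + 2 * k
    return out if out.ndim else float(out)


def unique_variance(
    full_r2: np.ndarray, partial_r2: Mapping[str, np.ndarray], floor: bool = True
) -> dict:
    """Unique r² per predictor set: r²_full − r²_partial (floored at 0)."""
    full_r2 = np.asarray(full_r2)
    out = {}
    for name, pr2 in partial_r2.items():
        pr2 = np.asarray(pr2)
        if pr2.shape != full_r2.shape:
            raise ValueError(f"partial model {name!r} shape mismatch")
        u = full_r2 - pr2
        out[name] = np.maximum(u, 0.0) if floor else u
    return out


def compute_snr(dataset: ERPDataset) -> np.ndarray:
    """Per-subject SNR: evoked post-stimulus amplitude over baseline SD.

    Per electrode, the image-mean ERP is averaged over post-stimulus
    timepoints; its absolute value is divided by the SD of the pre-stimulus
    timepoints of the same image-mean trace, then averaged over electrodes.
    """
    pre = dataset.times_ms < 0
    post = dataset.times_ms >= 0
    if pre.sum() < 2:
        raise ValueError("no pre-stimulus baseline window in the epoch")
    mean_erp = dataset.amplitude.mean(axis=1)  # (S, E, T)
    post_mean = mean_erp[:, :, post].mean(axis=2)
    pre_sd = mean_erp[:, :, pre].std(axis=2, ddof=1)
    if np.any(pre_sd == 0):
        raise ValueError("zero baseline variance for at least one electrode")
    return (np.abs(post_mean) / pre_sd).mean(axis=1)


def select_electrodes(
    dataset: ERPDataset, sd_threshold: float | None = None
) -> list[str]:
    """Electrodes with high amplitude SD across the whole dataset.

    With an explicit ``sd_threshold``, electrodes whose SD over all
    (subject, image, timepoint) samples exceeds it are returned.  The
    default (None) places the threshold at the largest gap in the sorted
    SDs, separating the high-variance (evoked-response) cluster from the
    rest without a hard-coded constant.
    """
    sd = dataset.amplitude.std(axis=(0, 1, 3))
    if sd_threshold is None:
        order = np.argsort(sd)
        gaps = np.diff(sd[order])
        split = int(np.argmax(gaps))
        sd_threshold = float((sd[order][split] + sd[order][split + 1]) / 2)
    if sd_threshold <= 0:
        raise ValueError("sd_threshold must be > 0")
    selected = [n for n, s in zip(dataset.electrode_names, sd) if s > sd_threshold]
    if not selected:
        raise ValueError(
            f"no electrode exceeds SD threshold {sd_threshold:.4g}; "
            "lower the threshold"
        )
    return selected


@dataclass
class TimeResolvedRDM:
    """Subject-averaged RDM stack with per-timepoint dissimilarity traces."""

    rdm: np.ndarray  # (T, I, I) subject-averaged
    times_ms: np.ndarray
    electrodes: list
    max_trace: np.ndarray  # (T,) max off-diagonal distance
    mean_trace: np.ndarray  # (T,) mean off-diagonal distance


def compute_rdms(
    dataset: ERPDataset,
    electrodes: Sequence[str] | None = None,
    subject_rdms: bool = False,
):
    """Time-resolved Euclidean-distance RDMs over electrode patterns.

    Per subject and timepoint, the RDM entry (i, j) is the Euclidean
    distance between the two images' amplitude patterns across the selected
    electrodes; the subject-average RDM is the elementwise mean.  Returns
    the averaged :class:`TimeResolvedRDM`, and the per-subject stack too if
    ``subject_rdms`` is set.
    """
    if electrodes is None:
        electrodes = select_electrodes(dataset)
    idx = dataset.electrode_index(electrodes)
    if len(idx) < 2:
        raise ValueError("need at least 2 electrodes")
    amp = dataset.amplitude[:, :, idx, :]  # (S, I, E, T)
    s, n_img, _, t = amp.shape
    mean_rdm = np.zeros((t, n_img, n_img))
    per_subject = np.zeros((s, t, n_img, n_img)) if subject_rdms else None
    for si in range(s):
        for ti in range(t):
            pat = amp[si, :, :, ti]  # (I, E)
            sq = (pat**2).sum(axis=1)
            d2 = sq[:, None] + sq[None, :] - 2.0 * pat @ pat.T
            d = np.sqrt(np.clip(d2, 0.0, None))
            np.fill_diagonal(d, 0.0)
            d = 0.5 * (d + d.T)
            mean_rdm[ti] += d
            if subject_rdms:
                per_subject[si, ti] = d
    mean_rdm /= s
    iu = np.triu_indices(n_img, k=1)
    tri = mean_rdm[:, iu[0], iu[1]]
    out = TimeResolvedRDM(
        rdm=mean_rdm,
        times_ms=np.asarray(dataset.times_ms),
        electrodes=list(electrodes),
        max_trace=tri.max(axis=1),
        mean_trace=tri.mean(axis=1),
    )
    return (out, per_subject) if subject_rdms else out


@dataclass
class RDMStatisticCorrelation:
    name: str
    r_m: np.ndarray  # (T,)
    p_values: np.ndarray  # (T,)
    peak_time_ms: float
    peak_index: int
    peak_result: MantelResult


def rdm_statistics_correlation(
    rdms: TimeResolvedRDM,
    distance_matrices: Mapping[str, np.ndarray],
    n_permutations: int = 1000,
    seed: int | None = None,
    n_boot: int = 0,
) -> dict[str, RDMStatisticCorrelation]:
    """Time-resolved Mantel correlation of the RDM with each statistic space.

    The permutation null is vectorized over timepoints: each simultaneous
    row/column permutation of the statistic matrix is correlated against
    every timepoint's RDM triangle at once.  A percentile-bootstrap CI on
    the dissimilarity values is computed at the peak timepoint when
    ``n_boot`` > 0.
    """
    from .similarity import mantel_bootstrap_ci

    t, n, _ = rdms.rdm.shape
    iu = np.triu_indices(n, k=1)
    tri = rdms.rdm[:, iu[0], iu[1]]  # (T, M)
    tri_c = tri - tri.mean(axis=1, keepdims=True)
    tri_norm = np.linalg.norm(tri_c, axis=1)
    if np.any(tri_norm == 0):
        raise ValueError("zero-variance RDM triangle at some timepoint")

    rng = np.random.default_rng(seed)
    out = {}
    for name, dmat in distance_matrices.items():
        dmat = _check_distance_matrix(dmat, name)
        vb = dmat[iu]
        vb_c = vb - vb.mean()
        vb_norm = np.linalg.norm(vb_c)
        r_obs = tri_c @ vb_c / (tri_norm * vb_norm)

        count = np.zeros(t)
        for _ in range(n_permutations):
            p = rng.permutation(n)
            vp = dmat[np.ix_(p, p)][iu]
            vp_c = vp - vp.mean()
            r_perm = tri_c @ vp_c / (tri_norm * np.linalg.norm(vp_c))
            count += r_perm >= r_obs
        p_values = (1 + count) / (1 + n_permutations)

        peak = int(np.argmax(r_obs))
        peak_res = MantelResult(
            float(r_obs[peak]), float(p_values[peak]), n_permutations
        )
        if n_boot > 0:
            lo, hi = mantel_bootstrap_ci(
                rdms.rdm[peak], dmat, n_boot=n_boot, seed=seed
            )
            peak_res.ci_low, peak_res.ci_high = lo, hi
        out[name] = RDMStatisticCorrelation(
            name=name,
            r_m=r_obs,
            p_values=p_values,
            peak_time_ms=float(rdms.times_ms[peak]),
            peak_index=peak,
            peak_result=peak_res,
        )
    return out
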