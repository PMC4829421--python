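"""Phasor-space analysis of fluorescence-lifetime (FLIM) decay data.

The phasor transform maps a photon-arrival histogram onto a point
(g, s) given by the cosine and sine Fourier components at a harmonic of
the laser repetition rate.  Single-exponential decays of lifetime tau lie
on the universal semicircle (g - 1/2)^2 + s^2 = 1/4; mixtures fall inside
it, at the intensity-weighted linear combination of the pure-species
positions.  Because retinoic acid (RA) is intrinsically fluorescent with a
distinctively short lifetime, the Cartesian distance d_RA from a measured
phasor to the pure-RA reference — the plot has unit diameter — yields a
relative-abundance statistic 1 - d_RA in [0, 1].
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "DecayCube",
    "PhasorPoint",
    "ReferenceSet",
    "AbundanceEstimate",
    "MixtureFractions",
    "ShotNoiseBound",
    "compute_phasor",
    "phasor_map",
    "phasor_of_lifetime",
    "harmonic_frequency",
    "total_integration_minutes",
    "relative_abundance",
    "unmix",
    "mix_phasors",
    "shot_noise_bound",
    "harmonic_consistency",
    "read_decay_cube",
    "write_decay_cube",
    "read_reference_table",
    "write_reference_table",
    "references_from_cubes",
]


class EmptySignalError(ValueError):
    """Raised when a phasor is requested for a region with zero photons."""


class DegenerateReferencesError(ValueError):
    """Raised when unmixing references are coincident or collinear."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DecayCube:
    """Per-pixel photon-arrival histograms with acquisition metadata.

    Parameters
    ----------
    counts
        Non-negative integer array of shape ``(n_bins, ny, nx)``; page k
        holds the photons that arrived in time bin k.
    rep_rate
        Laser pulse repetition rate in MHz (one laser period spans the
        full histogram).
    bin_width
        Width of one time bin in ns; ``bin_width * n_bins`` must equal the
        laser period ``1e3 / rep_rate`` ns.
    meta
        Free-form acquisition annotations (excitation wavelength, filters).
    """

    counts: np.ndarray
    rep_rate: float
    bin_width: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 3:
            raise ValueError(f"counts must be (n_bins, ny, nx), got {counts.shape}")
        if counts.size and counts.min() < 0:
            raise ValueError("photon counts must be non-negative")
        if self.n_bins < 4:
            raise ValueError("need at least 4 time bins")
        period_ns = 1e3 / self.rep_rate
        if not np.isclose(self.bin_width * self.n_bins, period_ns, rtol=1e-9):
            raise ValueError(
                f"bin_width * n_bins = {self.bin_width * self.n_bins:g} ns does "
                f"not match the laser period {period_ns:g} ns"
            )
        object.__setattr__(self, "counts", counts)

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def bin_centers(self) -> np.ndarray:
        """Bin-center times in ns (midpoint convention)."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_width

    @property
    def total_counts(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class PhasorPoint:
    """A point (g, s) in phasor space at a given harmonic."""

    g: float
    s: float
    harmonic: int = 1
    total_counts: int = 0

    @property
    def coords(self) -> np.ndarray:
        return np.array([self.g, self.s], dtype=float)

    def distance_to(self, other: "PhasorPoint") -> float:
        return float(np.hypot(self.g - other.g, self.s - other.s))


@dataclass(frozen=True)
class ReferenceSet:
    """Named pure-species phasor anchors sharing one harmonic.

    The RA entry must sit in the high-g, low-s region of the plot (short
    lifetime); this is validated on construction.
    """

    entries: tuple
    harmonic: int = 1
    ra_label: str = "RA"

    def __post_init__(self) -> None:
        entries = tuple((str(name), pt) for name, pt in self.entries)
        if len(entries) < 1:
            raise ValueError("need at least one reference entry")
        for name, pt in entries:
            if pt.harmonic != self.harmonic:
                raise ValueError(
                    f"reference {name!r} is at harmonic {pt.harmonic}, "
                    f"set declares {self.harmonic}"
                )
        by_name = dict(entries)
        if self.ra_label in by_name:
            ra = by_name[self.ra_label]
            if not (ra.g > 0.5 and ra.s < 0.5):
                raise ValueError(
                    "the RA reference must lie in the high-g, low-s "
                    f"(short lifetime) region; got (g={ra.g:g}, s={ra.s:g})"
                )
        object.__setattr__(self, "entries", entries)

    @property
    def labels(self) -> tuple:
        return tuple(name for name, _ in self.entries)

    @property
    def points(self) -> tuple:
        return tuple(pt for _, pt in self.entries)

    def __getitem__(self, label: str) -> PhasorPoint:
        for name, pt in self.entries:
            if name == label:
                return pt
        raise KeyError(label)

    def __contains__(self, label: str) -> bool:
        return label in self.labels

    @property
    def ra(self) -> PhasorPoint:
        return self[self.ra_label]


@dataclass(frozen=True)
class AbundanceEstimate:
    """Distance-based relative abundance 1 - d_RA."""

    one_minus_d: float
    d_ra: float
    harmonic: int


@dataclass(frozen=True)
class MixtureFractions:
    """Intensity fractions per species; non-negative, summing to one."""

    fractions: Mapping[str, float]
    residual: float = 0.0

    def __post_init__(self) -> None:
        fr = dict(self.fractions)
        vals = np.array(list(fr.values()), dtype=float)
        if vals.size and (vals < -1e-9).any():
            raise ValueError("fractions must be non-negative")
        if vals.size and abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {vals.sum():.12g}")
        object.__setattr__(self, "fractions", fr)

    def __getitem__(self, label: str) -> float:
        return self.fractions[label]


@dataclass(frozen=True)
class ShotNoiseBound:
    """Photon shot-noise standard deviations of the phasor coordinates."""

    sigma_g: float
    sigma_s: float
    n_photons: float
    harmonic: int

    @property
    def sigma(self) -> float:
        """Radial (combined) standard deviation sqrt(sg^2 + ss^2)."""
        return float(np.hypot(self.sigma_g, self.sigma_s))


# --------------------------------------------------------------------------
# core transforms
# --------------------------------------------------------------------------

def _angular_frequency(rep_rate: float, harmonic: int) -> float:
    """Angular frequency n * 2*pi*f in rad/ns for rep_rate in MHz."""
    return 2.0 * np.pi * rep_rate * 1e-3 * harmonic


def compute_phasor(
    cube: DecayCube,
    harmonic: int = 1,
    mask: np.ndarray | None = None,
) -> PhasorPoint:
    """Aggregate photons over a pixel region and transform to phasor space.

    g = sum_k I_k cos(n w t_k) / sum_k I_k and likewise with sine, with
    w = 2 pi * rep_rate and t_k the bin centers.  Photons are pooled over
    the masked region before transforming (region phasor); use
    :func:`phasor_map` for per-pixel maps.

    Raises
    ------
    EmptySignalError
        If the masked region contains no photons.
    """
    if harmonic < 1:
        raise ValueError("harmonic must be >= 1")
    if harmonic > cube.n_bins // 2:
        warnings.warn(
            f"harmonic {harmonic} exceeds the Nyquist bin spacing for "
            f"{cube.n_bins} bins; phasor coordinates will be aliased",
            stacklevel=2,
        )
    counts = cube.counts
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != counts.shape[1:]:
            raise ValueError("mask shape must match the (y, x) image shape")
        hist = counts[:, mask].sum(axis=1)
    else:
        hist = counts.reshape(cube.n_bins, -1).sum(axis=1)
    total = float(hist.sum())
    if total <= 0:
        raise EmptySignalError("no photons in the selected region")
    w = _angular_frequency(cube.rep_rate, harmonic)
    t = cube.bin_centers
    g = float(np.dot(hist, np.cos(w * t)) / total)
    s = float(np.dot(hist, np.sin(w * t)) / total)
    return PhasorPoint(g=g, s=s, harmonic=harmonic, total_counts=int(total))


def phasor_map(cube: DecayCube, harmonic: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel phasor coordinates; pixels with zero photons yield NaN."""
    w = _angular_frequency(cube.rep_rate, harmonic)
    t = cube.bin_centers
    counts = cube.counts.astype(float)
    total = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.tensordot(np.cos(w * t), counts, axes=(0, 0)) / total
        s = np.tensordot(np.sin(w * t), counts, axes=(0, 0)) / total
    g[total == 0] = np.nan
    s[total == 0] = np.nan
    return g, s


def phasor_of_lifetime(tau: float, rep_rate: float = 80.0, harmonic: int = 1) -> PhasorPoint:
    """Closed-form phasor of a single-exponential decay.

    Returns (1/(1+(n w tau)^2), n w tau/(1+(n w tau)^2)), which lies
    exactly on the universal semicircle for every tau >= 0.
    """
    if tau < 0:
        raise ValueError("lifetime must be non-negative")
    if rep_rate <= 0 or harmonic < 1:
        raise ValueError("rep_rate must be positive and harmonic >= 1")
    wt = _angular_frequency(rep_rate, harmonic) * tau
    denom = 1.0 + wt * wt
    return PhasorPoint(g=1.0 / denom, s=wt / denom, harmonic=harmonic)


def harmonic_frequency(rep_rate: float, harmonic: int) -> float:
    """Frequency of the n-th harmonic of the laser pulse rate, in MHz."""
    if rep_rate <= 0 or harmonic < 1:
        raise ValueError("rep_rate must be positive and harmonic >= 1")
    return float(rep_rate * harmonic)


def total_integration_minutes(n_frames: int, frame_seconds: float) -> float:
    """Total integration time of consecutive frames, in minutes."""
    if n_frames < 1 or frame_seconds <= 0:
        raise ValueError("need n_frames >= 1 and positive frame time")
    return n_frames * frame_seconds / 60.0


# --------------------------------------------------------------------------
# abundance and unmixing
# --------------------------------------------------------------------------

def relative_abundance(measured: PhasorPoint, refs: ReferenceSet) -> AbundanceEstimate:
    """Relative RA abundance as 1 minus the distance to the RA reference.

    The phasor plot has unit diameter, so the Cartesian distance d_RA from
    the measured point to the pure-RA anchor lies in [0, 1] for physical
    points; 1 - d_RA is clipped at 0 (with a logged warning) if measurement
    noise pushes a point outside the plot.
    """
    if measured.harmonic != refs.harmonic:
        raise ValueError(
            f"harmonic mismatch: measured {measured.harmonic}, refs {refs.harmonic}"
        )
    if refs.ra_label not in refs:
        raise ValueError(f"reference set has no {refs.ra_label!r} entry")
    d = measured.distance_to(refs.ra)
    if d > 1.0:
        logger.warning(
            "d_RA = %.4f exceeds the unit plot diameter; clipping 1-d_RA to 0", d
        )
    return AbundanceEstimate(
        one_minus_d=float(np.clip(1.0 - d, 0.0, 1.0)),
        d_ra=float(d),
        harmonic=measured.harmonic,
    )


def mix_phasors(points: Sequence[PhasorPoint], fractions: Sequence[float]) -> PhasorPoint:
    """Intensity-weighted linear combination of phasor points."""
    f = np.asarray(fractions, dtype=float)
    if len(points) != f.size:
        raise ValueError("points and fractions must align")
    if abs(f.sum() - 1.0) > 1e-9 or (f < -1e-12).any():
        raise ValueError("fractions must be a convex combination")
    coords = np.array([[p.g, p.s] for p in points])
    g, s = f @ coords
    return PhasorPoint(g=float(g), s=float(s), harmonic=points[0].harmonic)


def unmix(measured: PhasorPoint, refs: ReferenceSet) -> MixtureFractions:
    """Recover intensity fractions of 2-3 pure species from a mixed phasor.

    Solves min ||sum_i f_i P_i - m||^2 subject to sum f_i = 1, f_i >= 0 by
    enumerating active sets (exact for <= 3 species); ties are broken by
    the minimal-norm solution, so output is deterministic.  A point far
    outside the reference hull is still unmixed, with a large residual
    reported and a warning logged.
    """
    k = len(refs.entries)
    if k not in (2, 3):
        raise ValueError("unmixing requires 2 or 3 references")
    P = np.array([[p.g, p.s] for p in refs.points])  # (k, 2)
    # affine independence: rank of displacement matrix must be k - 1
    disp = P[1:] - P[0]
    if np.linalg.matrix_rank(disp, tol=1e-10) < k - 1:
        kind = "coincident" if k == 2 else "collinear"
        raise DegenerateReferencesError(f"reference positions are {kind}")
    m = measured.coords

    best: tuple[float, float, np.ndarray] | None = None
    for inactive in itertools.chain.from_iterable(
        itertools.combinations(range(k), r) for r in range(0, k)
    ):
        free = [i for i in range(k) if i not in inactive]
        A = P[free].T  # (2, n_free)
        nf = len(free)
        # KKT system for min ||A f - m||^2 s.t. 1'f = 1
        kkt = np.zeros((nf + 1, nf + 1))
        kkt[:nf, :nf] = A.T @ A + 1e-12 * np.eye(nf)
        kkt[:nf, nf] = 1.0
        kkt[nf, :nf] = 1.0
        rhs = np.concatenate([A.T @ m, [1.0]])
        try:
            sol = np.linalg.solve(kkt, rhs)
        except np.linalg.LinAlgError:
            continue
        f_free = sol[:nf]
        if (f_free < -1e-9).any():
            continue
        f = np.zeros(k)
        f[free] = np.clip(f_free, 0.0, None)
        f /= f.sum()
        resid = float(np.linalg.norm(P.T @ f - m))
        key = (round(resid, 12), float(np.dot(f, f)))
        if best is None or key < (round(best[0], 12), best[1]):
            best = (resid, key[1], f)
    assert best is not None
    resid, _, f = best
    if resid > 0.05:
        logger.warning(
            "measured phasor lies outside the reference hull "
            "(residual %.4f phasor units)", resid
        )
    return MixtureFractions(
        fractions=dict(zip(refs.labels, (float(x) for x in f))),
        residual=resid,
    )


# --------------------------------------------------------------------------
# shot noise
# --------------------------------------------------------------------------

def _wrapped_exponential(tau: float, rep_rate: float, n_bins: int) -> np.ndarray:
    """Normalized bin probabilities of a periodically wrapped exponential."""
    period = 1e3 / rep_rate
    t = (np.arange(n_bins) + 0.5) * (period / n_bins)
    p = np.exp(-t / tau) if tau > 0 else np.r_[1.0, np.zeros(n_bins - 1)]
    return p / p.sum()


def shot_noise_bound(
    n_photons: float,
    harmonic: int = 1,
    *,
    decay: np.ndarray | None = None,
    tau: float | None = None,
    rep_rate: float = 80.0,
    n_bins: int = 256,
) -> ShotNoiseBound:
    """Theoretical phasor-coordinate uncertainty from photon shot noise.

    Propagates Poisson counting noise through the phasor ratio estimator
    by the delta method: for bin probabilities p_k and total expected
    counts N, Var(g) = sum_k p_k (cos(n w t_k) - g)^2 / N (and likewise
    for s), so both standard deviations scale as N^(-1/2).

    The decay shape defaults to a wrapped single exponential at the
    semicircle midpoint (n w tau = 1), a representative near-worst case;
    pass ``decay`` (a histogram) or ``tau`` to evaluate a specific shape.
    """
    if n_photons < 1:
        raise ValueError("need at least one expected photon")
    if decay is not None:
        p = np.asarray(decay, dtype=float)
        p = p / p.sum()
        n_bins = p.size
    else:
        if tau is None:
            tau = 1.0 / _angular_frequency(rep_rate, harmonic)
        p = _wrapped_exponential(tau, rep_rate, n_bins)
    period = 1e3 / rep_rate
    t = (np.arange(n_bins) + 0.5) * (period / n_bins)
    w = _angular_frequency(rep_rate, harmonic)
    c, s_ = np.cos(w * t), np.sin(w * t)
    g0, s0 = float(p @ c), float(p @ s_)
    var_g = float(p @ (c - g0) ** 2) / n_photons
    var_s = float(p @ (s_ - s0) ** 2) / n_photons
    return ShotNoiseBound(
        sigma_g=float(np.sqrt(var_g)),
        sigma_s=float(np.sqrt(var_s)),
        n_photons=float(n_photons),
        harmonic=harmonic,
    )


# --------------------------------------------------------------------------
# harmonic cross-check
# --------------------------------------------------------------------------

def harmonic_consistency(
    cube_series: Sequence[DecayCube],
    refs_h1: ReferenceSet,
    refs_h3: ReferenceSet,
) -> pd.DataFrame:
    """Paired relative abundance at two harmonics with their association.

    Analyzing a different harmonic decouples d_RA from the other mixture
    components, so a real abundance gradient must agree across harmonics.
    Returns a table of 1-d_RA per cube at both harmonics; the Spearman
    rank correlation and its sign are stored in ``df.attrs``.
    """
    if len(cube_series) < 3:
        raise ValueError("need at least 3 cubes for a rank association")
    rows = []
    for i, cube in enumerate(cube_series):
        a1 = relative_abundance(compute_phasor(cube, refs_h1.harmonic), refs_h1)
        a3 = relative_abundance(compute_phasor(cube, refs_h3.harmonic), refs_h3)
        rows.append(
            {"cube": i, "one_minus_d_h1": a1.one_minus_d, "one_minus_d_h3": a3.one_minus_d}
        )
    df = pd.DataFrame(rows)
    rho, p = stats.spearmanr(df["one_minus_d_h1"], df["one_minus_d_h3"])
    df.attrs["spearman_rho"] = float(rho)
    df.attrs["spearman_p"] = float(p)
    df.attrs["association_sign"] = int(np.sign(rho)) if np.isfinite(rho) else 0
    return df


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def write_decay_cube(path: str | Path, cube: DecayCube) -> None:
    """Write a decay cube as multi-page TIFF + JSON sidecar, or as .npz."""
    import tifffile

    path = Path(path)
    meta = {
        "rep_rate_mhz": cube.rep_rate,
        "n_bins": cube.n_bins,
        "bin_width_ns": cube.bin_width,
        "meta": cube.meta,
    }
    if path.suffix == ".npz":
        np.savez(path, counts=cube.counts, meta_json=json.dumps(meta))
    else:
        tifffile.imwrite(path, cube.counts.astype(np.uint16))
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_decay_cube(path: str | Path) -> DecayCube:
    import tifffile

    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            counts = z["counts"]
            meta = json.loads(str(z["meta_json"]))
    else:
        counts = tifffile.imread(path)
        meta = json.loads(path.with_suffix(".json").read_text())
    return DecayCube(
        counts=counts,
        rep_rate=meta["rep_rate_mhz"],
        bin_width=meta["bin_width_ns"],
        meta=meta.get("meta", {}),
    )


def write_reference_table(path: str | Path, refs: ReferenceSet) -> None:
    df = pd.DataFrame(
        [{"species": n, "g": p.g, "s": p.s, "harmonic": p.harmonic} for n, p in refs.entries]
    )
    df.to_csv(path, index=False)


def read_reference_table(path: str | Path, ra_label: str = "RA") -> ReferenceSet:
    df = pd.read_csv(path)
    harmonic = int(df["harmonic"].iloc[0])
    entries = [
        (row["species"], PhasorPoint(g=row["g"], s=row["s"], harmonic=int(row["harmonic"])))
        for _, row in df.iterrows()
    ]
    return ReferenceSet(entries=tuple(entries), harmonic=harmonic, ra_label=ra_label)


def references_from_cubes(
    cubes: Mapping[str, DecayCube], harmonic: int = 1, ra_label: str = "RA"
) -> ReferenceSet:
    """Anchor a reference set by transforming pure-species decay cubes."""
    entries = tuple((name, compute_phasor(c, harmonic)) for name, c in cubes.items())
    return ReferenceSet(entries=entries, harmonic=harmonic, ra_label=ra_label)
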