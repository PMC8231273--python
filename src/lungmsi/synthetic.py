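"""Seeded synthetic MSI cohorts emulating drug-distribution patterns in lung.

No raw acquisitions are publicly deposited for this kind of study, so the
pipeline is exercised on synthetic sections that reproduce the *structure*
the analysis assumes: an irregular, non-convex lobe outline on a 400 µm
raster (~50 x 20 mm section); a heme channel present only on tissue; an
internal-standard channel on every tissue pixel; and a drug channel whose
spatial field follows one of four treatment-like patterns:

``clumpy``
    few large, centrally placed intensity foci (drug in saline vehicle,
    1 min of ventilation);
``dispersed``
    many small foci biased toward the tissue border (drug spread by
    surfactant, 1 min);
``cleared``
    the dispersed field scaled down by ``clearance_fraction`` (default
    0.93, the ~93% two-hour lung clearance of budesonide);
``control``
    no drug signal at all (vehicle-only animals used to set the detection
    threshold).

The drug field is a sum of isotropic super-Gaussian (quartic) foci on the
tissue mask — plateaus with steep edges, like discrete instilled-bolus
patches — under multiplicative log-normal pixel noise.  Clumpy foci keep a
minimum center-to-center spacing, as separate boluses do.  Chemical noise is
modelled two ways:
sparse random centroids across the full m/z range on every pixel, and a
sparse log-normal baseline *inside* the drug's extraction window on tissue
pixels.  The latter is what a control section's violin plot shows and what
the control-derived detection threshold is estimated from; its upper tail is
wide enough that the 93%-cleared signal falls mostly below the threshold, as
the study's 120-min sections do.  Setting ``noise_cv=0`` produces a fully
noiseless section (all noise sources off), used by ground-truth tests.

A companion SP-C dataset (m/z 2000-5000, peak at 4188) shares the section
geometry — consecutive 20 µm sections are near-identical at this raster —
and mixes the drug field with an independent field according to
``spc_coupling``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .imzml import CentroidSpectrum, MSIDataset
from .ionmap import DEFAULT_TARGETS, TissueMask

__all__ = ["GeneratorParams", "generate_tissue_mask", "generate_section", "generate_cohort"]

PATTERNS = ("clumpy", "dispersed", "cleared", "control")

#: per-pattern defaults: (n_blobs, blob_sigma_mm, peripheral_bias)
_PATTERN_DEFAULTS = {
    "clumpy": (8, 2.0, 0.0),
    "dispersed": (60, 0.8, 0.7),
    "cleared": (60, 0.8, 0.7),
    "control": (0, 1.0, 0.0),
}

#: minimum center-to-center spacing of clumpy foci, in units of blob sigma
#: (instilled boluses are spatially distinct patches, not an overlapping pile)
_CLUMPY_MIN_SEP_SIGMA = 3.0

#: fraction of tissue pixels carrying an in-window chemical-baseline peak
_BASELINE_FRACTION = 0.03
#: log-normal parameters of that baseline, relative to base_intensity
_BASELINE_MEDIAN = 0.10
_BASELINE_SIGMA = 0.7
#: focus-center peripheral weighting length scale, mm
_PERIPHERAL_LAMBDA_MM = 2.0
#: heme channel amplitude relative to base_intensity
_HEME_LEVEL = 0.5
#: SP-C channel amplitude relative to base_intensity
_SPC_LEVEL = 0.3
#: off-tissue / broadband chemical-noise peak intensity, relative
_CHEM_NOISE_LEVEL = 0.001

_BUD_MZ = DEFAULT_TARGETS["budesonide"].target_mz
_IS_MZ = DEFAULT_TARGETS["internal_standard"].target_mz
_HEME_MZ = DEFAULT_TARGETS["heme"].target_mz
_SPC_MZ = DEFAULT_TARGETS["spc"].target_mz


@dataclass(frozen=True)
class GeneratorParams:
    """Study-condition parameters of one synthetic section.

    ``n_blobs``, ``blob_sigma_mm`` and ``peripheral_bias`` default to
    pattern-specific values when left as ``None``.
    """

    pattern: str = "dispersed"
    grid_shape: tuple[int, int] = (50, 125)  # (rows, cols) ~ 20 x 50 mm
    pixel_pitch_um: float = 400.0
    n_blobs: int | None = None
    blob_sigma_mm: float | None = None
    peripheral_bias: float | None = None
    base_intensity: float = 1000.0
    noise_cv: float = 0.15
    clearance_fraction: float = 0.93
    spc_coupling: float = 0.8
    budesonide_amplitude: float | None = None  # override; must be 0/None for control
    seed: int = 0

    def resolved(self) -> "GeneratorParams":
        """Fill pattern-dependent defaults and validate."""
        if self.pattern not in PATTERNS:
            raise ValueError(f"pattern must be one of {PATTERNS}, got {self.pattern!r}")
        nb, sig, bias = _PATTERN_DEFAULTS[self.pattern]
        out = replace(
            self,
            n_blobs=self.n_blobs if self.n_blobs is not None else nb,
            blob_sigma_mm=self.blob_sigma_mm if self.blob_sigma_mm is not None else sig,
            peripheral_bias=self.peripheral_bias if self.peripheral_bias is not None else bias,
        )
        rows, cols = out.grid_shape
        if rows < 4 or cols < 4:
            raise ValueError(f"grid_shape {out.grid_shape} too small; need at least 4x4 pixels")
        for name in ("clearance_fraction", "peripheral_bias", "spc_coupling"):
            val = getattr(out, name)
            if not 0 <= val <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {val}")
        if out.blob_sigma_mm <= 0:
            raise ValueError("blob_sigma_mm must be positive")
        if out.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if out.pattern == "control" and out.budesonide_amplitude:
            raise ValueError("control sections cannot carry a nonzero drug amplitude")
        return out


def _radial_mask(params: GeneratorParams, rng: np.random.Generator) -> np.ndarray:
    """Star-shaped lobe outline with random harmonics and a guaranteed notch."""
    rows, cols = params.grid_shape
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    ay, ax = 0.40 * rows, 0.44 * cols  # semi-axes, pixels
    Y, X = np.mgrid[0:rows, 0:cols]
    dy, dx = Y - cy, X - cx
    theta = np.arctan2(dy, dx)
    rho = np.ones_like(theta)
    for k in range(2, 5):
        amp = rng.uniform(-0.08, 0.08)
        phase = rng.uniform(0, 2 * np.pi)
        rho += amp * np.cos(k * theta + phase)
    # notch: a wedge-shaped bite so the outline always has a concavity
    theta0 = rng.uniform(-np.pi, np.pi)
    dtheta = np.angle(np.exp(1j * (theta - theta0)))
    rho -= 0.30 * np.exp(-((dtheta / 0.45) ** 2))
    # boundary radius along each direction for an ellipse scaled by rho
    with np.errstate(divide="ignore"):
        r_dir = rho / np.sqrt((np.cos(theta) / ax) ** 2 + (np.sin(theta) / ay) ** 2)
    dist = np.hypot(dy, dx)
    mask = dist <= r_dir
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
        mask = labels == (int(np.argmax(sizes)) + 1)
    return mask


def generate_tissue_mask(params: GeneratorParams) -> TissueMask:
    """The section's ground-truth tissue mask, reproducible from the seed."""
    params = params.resolved()
    rng_mask, *_ = _channel_rngs(params.seed)
    return TissueMask(_radial_mask(params, rng_mask), source="synthetic")


def _channel_rngs(seed: int) -> list[np.random.Generator]:
    """Independent streams for mask, fields, and per-dataset assembly.

    Separate streams keep the budesonide dataset bit-identical whether or
    not the SP-C companion is generated, and the mask identical across
    patterns at a fixed seed.
    """
    children = np.random.SeedSequence(seed).spawn(4)
    return [np.random.default_rng(c) for c in children]


def _sample_focus_centers(
    mask: np.ndarray,
    n: int,
    bias: float,
    pitch_mm: float,
    rng: np.random.Generator,
    min_sep_px: float = 0.0,
) -> np.ndarray:
    """(n, 2) focus centers (x, y in pixels) on tissue.

    Each focus is border-weighted with probability ``bias``; a positive
    ``min_sep_px`` enforces (best-effort, by rejection) a minimum
    center-to-center spacing.
    """
    ys, xs = np.nonzero(mask)
    d_border = ndimage.distance_transform_edt(mask)[ys, xs] * pitch_mm
    w_periph = np.exp(-d_border / _PERIPHERAL_LAMBDA_MM)
    w_periph /= w_periph.sum()
    centers = np.empty((n, 2))
    for i in range(n):
        for _attempt in range(200):
            if rng.uniform() < bias:
                j = rng.choice(ys.size, p=w_periph)
            else:
                j = rng.integers(ys.size)
            cand = np.array([xs[j], ys[j]], dtype=float)
            if min_sep_px <= 0 or i == 0:
                break
            if np.min(np.hypot(*(centers[:i] - cand).T)) >= min_sep_px:
                break
        centers[i] = cand
    return centers


def _build_fields(params: GeneratorParams, mask: np.ndarray, rng: np.random.Generator):
    """Noiseless normalized drug field, companion SP-C field, and noise grids.

    All random draws happen in a fixed order regardless of pattern so that a
    seed-matched ``cleared`` section reuses exactly the ``dispersed``
    geometry and noise.
    """
    rows, cols = params.grid_shape
    pitch_mm = params.pixel_pitch_um / 1000.0
    Y, X = np.mgrid[0:rows, 0:cols]

    def focus_sum(centers: np.ndarray, amps: np.ndarray, sig_px: float) -> np.ndarray:
        # super-Gaussian (quartic) profile: a plateau with steep edges, like
        # a discrete instilled-drug patch; steep edges keep the quartile cut
        # out of wide shallow-gradient bands where pixel noise would
        # fragment clump boundaries into speckle
        out = np.zeros((rows, cols))
        for (cx, cy), amp in zip(centers, amps):
            r2 = ((X - cx) ** 2 + (Y - cy) ** 2) / (2 * sig_px**2)
            out += amp * np.exp(-(r2**2))
        return out

    sig_px = params.blob_sigma_mm / pitch_mm
    min_sep_px = _CLUMPY_MIN_SEP_SIGMA * sig_px if params.pattern == "clumpy" else 0.0
    field = np.zeros((rows, cols))
    if params.n_blobs:
        centers = _sample_focus_centers(
            mask, params.n_blobs, params.peripheral_bias, pitch_mm, rng, min_sep_px
        )
        amps = rng.uniform(0.8, 1.2, size=params.n_blobs)
        field = focus_sum(centers, amps, sig_px)
    field[~mask] = 0.0
    field[field < 1e-9] = 0.0  # consistent zero set across channels

    def lognoise(cv: float, shape) -> np.ndarray:
        draw = rng.standard_normal(shape)  # always drawn: keeps streams aligned
        if cv == 0:
            return np.ones(shape)
        sigma = np.sqrt(np.log1p(cv**2))
        return np.exp(sigma * draw - sigma**2 / 2)

    noise_bud = lognoise(params.noise_cv, (rows, cols))
    noise_is = lognoise(0.3 * params.noise_cv, (rows, cols))
    noise_heme = lognoise(1.2 * params.noise_cv, (rows, cols))

    # sparse in-window chemical baseline (the control "violin" signal)
    bl_sel = rng.uniform(size=(rows, cols)) < _BASELINE_FRACTION
    bl_val = _BASELINE_MEDIAN * np.exp(_BASELINE_SIGMA * rng.standard_normal((rows, cols)))
    baseline = np.where(bl_sel & mask, bl_val, 0.0)
    if params.noise_cv == 0:
        baseline = np.zeros_like(baseline)

    # independent field for the SP-C mixture, same pattern geometry
    indep = np.zeros((rows, cols))
    if params.n_blobs:
        centers2 = _sample_focus_centers(
            mask, params.n_blobs, params.peripheral_bias, pitch_mm, rng, min_sep_px
        )
        amps2 = rng.uniform(0.8, 1.2, size=params.n_blobs)
        indep = focus_sum(centers2, amps2, sig_px)
    indep[~mask] = 0.0
    indep[indep < 1e-9] = 0.0
    noise_spc = lognoise(params.noise_cv, (rows, cols))

    spc_field = params.spc_coupling * field + (1 - params.spc_coupling) * indep

    return field, spc_field, baseline, noise_bud, noise_is, noise_heme, noise_spc


def _noise_peaks(rng: np.random.Generator, mz_lo: float, mz_hi: float, level: float):
    """Sparse broadband chemical-noise centroids for one pixel."""
    k = int(rng.poisson(2.0))
    mzs = rng.uniform(mz_lo, mz_hi, size=k)
    ints = level * rng.uniform(0.5, 1.5, size=k)
    return mzs, ints


def _assemble(mz_list, int_list) -> CentroidSpectrum:
    mzs = np.concatenate([np.atleast_1d(np.asarray(m, dtype=float)) for m in mz_list])
    ints = np.concatenate([np.atleast_1d(np.asarray(i, dtype=float)) for i in int_list])
    keep = ints > 0
    mzs, ints = mzs[keep], ints[keep]
    order = np.argsort(mzs)
    mzs, ints = mzs[order], ints[order]
    # merge (astronomically rare) duplicate centroids to keep m/z strictly ascending
    if mzs.size > 1 and np.any(np.diff(mzs) == 0):
        uniq, inverse = np.unique(mzs, return_inverse=True)
        summed = np.zeros_like(uniq)
        np.add.at(summed, inverse, ints)
        mzs, ints = uniq, summed
    return CentroidSpectrum(mzs, ints)


def generate_section(params: GeneratorParams, analyte: str = "budesonide") -> MSIDataset:
    """One synthetic section as an in-memory MSI dataset.

    ``analyte='budesonide'`` gives the m/z 185-650 acquisition (drug +
    internal standard + heme + chemical noise); ``analyte='spc'`` gives the
    companion m/z 2000-5000 acquisition of the consecutive section, with the
    SP-C field coupled to the drug field by ``spc_coupling``.  The same seed
    reproduces the same section bit-for-bit, and both analytes share one
    underlying geometry.
    """
    if analyte not in ("budesonide", "spc"):
        raise ValueError(f"analyte must be 'budesonide' or 'spc', got {analyte!r}")
    params = params.resolved()
    rng_mask, rng_fields, rng_bud, rng_spc = _channel_rngs(params.seed)

    mask = _radial_mask(params, rng_mask)
    field, spc_field, baseline, noise_bud, noise_is, noise_heme, noise_spc = _build_fields(
        params, mask, rng_fields
    )

    A = params.base_intensity
    drug_amp = params.budesonide_amplitude
    if drug_amp is None:
        drug_amp = 0.0 if params.pattern == "control" else A
    scale = (1 - params.clearance_fraction) if params.pattern == "cleared" else 1.0

    rows, cols = params.grid_shape
    pixels: dict[tuple[int, int], CentroidSpectrum] = {}

    if analyte == "budesonide":
        rng_px = rng_bud
        mz_range = (185.0, 650.0)
        chem_level = _CHEM_NOISE_LEVEL * A
        for y in range(rows):
            for x in range(cols):
                nz_mz, nz_int = _noise_peaks(rng_px, *mz_range, chem_level)
                if params.noise_cv == 0:
                    nz_mz, nz_int = nz_mz[:0], nz_int[:0]
                if mask[y, x]:
                    bud = drug_amp * scale * field[y, x] * noise_bud[y, x] + A * baseline[y, x]
                    is_val = A * noise_is[y, x]
                    heme_val = _HEME_LEVEL * A * noise_heme[y, x]
                    spec = _assemble(
                        [nz_mz, [_BUD_MZ, _IS_MZ, _HEME_MZ]],
                        [nz_int, [bud, is_val, heme_val]],
                    )
                else:
                    spec = _assemble([nz_mz], [nz_int])
                pixels[(x, y)] = spec
    else:
        rng_px = rng_spc
        mz_range = (2000.0, 5000.0)
        chem_level = _CHEM_NOISE_LEVEL * _SPC_LEVEL * A
        for y in range(rows):
            for x in range(cols):
                nz_mz, nz_int = _noise_peaks(rng_px, *mz_range, chem_level)
                if params.noise_cv == 0:
                    nz_mz, nz_int = nz_mz[:0], nz_int[:0]
                if mask[y, x]:
                    spc_val = _SPC_LEVEL * A * spc_field[y, x] * noise_spc[y, x]
                    spec = _assemble([nz_mz, [_SPC_MZ]], [nz_int, [spc_val]])
                else:
                    spec = _assemble([nz_mz], [nz_int])
                pixels[(x, y)] = spec

    return MSIDataset(
        pixels=pixels,
        pixel_pitch_um=params.pixel_pitch_um,
        mz_range=mz_range,
        polarity="positive",
        section_id=f"{params.pattern}_s{params.seed}_{analyte}",
        group_label=params.pattern,
        grid_shape=params.grid_shape,
    )


#: cohort arm -> generator pattern
COHORT_GROUPS = (
    ("BUD_1min", "clumpy"),
    ("SF_BUD_1min", "dispersed"),
    ("SF_BUD_120min", "cleared"),
)
N_CONTROLS = 2


def generate_cohort(
    n_per_group: int,
    seed: int,
    base_params: GeneratorParams | None = None,
    analyte: str = "budesonide",
) -> list[MSIDataset]:
    """A labelled cohort: ``n_per_group`` sections per treatment arm plus
    two vehicle-only controls, each section with a distinct derived seed."""
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    base = base_params if base_params is not None else GeneratorParams()
    n_total = 3 * n_per_group + N_CONTROLS
    state = np.random.SeedSequence(seed).generate_state(2 * n_total, dtype=np.uint32)
    seeds: list[int] = []
    for s in state:  # drop the sign bit; skip (improbable) collisions
        v = int(s) >> 1
        if v not in seeds:
            seeds.append(v)
        if len(seeds) == n_total:
            break

    datasets = []
    i = 0
    for group, pattern in COHORT_GROUPS:
        for j in range(n_per_group):
            params = replace(base, pattern=pattern, seed=seeds[i])
            ds = generate_section(params, analyte=analyte)
            ds.section_id = f"{group}_{j + 1}"
            ds.group_label = group
            datasets.append(ds)
            i += 1
    for j in range(N_CONTROLS):
        params = replace(base, pattern="control", seed=seeds[i])
        ds = generate_section(params, analyte=analyte)
        ds.section_id = f"CTRL_{j + 1}"
        ds.group_label = "CTRL"
        datasets.append(ds)
        i += 1
    return datasets
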