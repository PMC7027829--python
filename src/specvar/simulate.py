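"""Synthetic hyperspectral landscapes with known α/β structure.

The simulator builds a small square region tiled into equal square
communities, each populated from a library of leaf-level reflectance
spectra (S species × I individuals). Two paired scenarios are produced:

* **high β** — one species is drawn per community (with configurable
  species probabilities), and every pixel of the community receives the
  spectrum of a random individual of that species. Communities are
  spectrally pure at the species level, so most spectral variance sits
  *among* communities.
* **low β** — the pixels of the high-β landscape are moved to uniformly
  random positions. The multiset of spectra — hence the total (γ) variance —
  is exactly preserved, but species are mixed within communities, moving the
  variance *within* them.

Leaf spectra are parametric stand-ins generated from a smooth continuum
(low visible reflectance, a red-edge rise to a NIR plateau, a declining
SWIR tail) minus Gaussian absorption features for photosynthetic pigments
(~450 and ~680 nm) and leaf water (~1450 and ~1940 nm). Species differ in
plateau height, red-edge position and feature depths; individuals of a
species jitter the feature depths and overall amplitude. Under the default
parameters individuals are spectrally closer to conspecifics than to other
species, which is what makes the species-pure scenario β-dominated.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .cube import SpectralCube
from .errors import ParameterError, ValidationError
from .partition import CommunityGrid, make_community_grid

#: Default wavelength grid: 400–2400 nm at 10 nm (201 bands), wide enough to
#: exercise the full preprocessing chain.
DEFAULT_WAVELENGTHS = np.arange(400.0, 2401.0, 10.0)

#: Community-level species probabilities of the standard two-scenario design.
DEFAULT_SPECIES_PROBS = (0.60, 0.35, 0.05)


@dataclass
class LeafSpectraLibrary:
    """S·I labeled leaf spectra on a common wavelength grid.

    ``spectra`` has shape (S·I, bands); row s*I + i is individual i of
    species s. Values lie in [0, 1].
    """

    wavelengths: np.ndarray
    spectra: np.ndarray
    species: np.ndarray  # (S*I,) species index of each spectrum
    individual: np.ndarray  # (S*I,) individual index within species
    n_species: int
    n_individuals: int

    def spectrum(self, species: int, individual: int) -> np.ndarray:
        return self.spectra[species * self.n_individuals + individual]


@dataclass
class LandscapeScenario:
    """A simulated region with per-pixel species/individual truth labels."""

    cube: SpectralCube
    pixel_species: np.ndarray  # (rows, cols)
    pixel_individual: np.ndarray  # (rows, cols)
    grid: CommunityGrid
    scenario: str  # "high_beta" | "low_beta"
    seed: int


# species archetypes: (nir_plateau, red_edge_nm, pigment&water feature depths);
# separation among species (plateau height, red-edge position, water-feature
# depth) is set clearly above the individual-level jitter, emulating temperate
# broadleaf taxa whose interspecific spectral differences dominate
# within-species variation
_SPECIES_PARAMS = [
    # (plateau, red_edge, [(center, depth, width), ...])
    (0.50, 712.0, [(450.0, 0.85, 35.0), (680.0, 0.88, 30.0),
                   (1450.0, 0.55, 55.0), (1940.0, 0.70, 70.0)]),
    (0.43, 728.0, [(450.0, 0.78, 40.0), (680.0, 0.80, 32.0),
                   (1450.0, 0.72, 50.0), (1940.0, 0.85, 65.0)]),
    (0.58, 704.0, [(450.0, 0.90, 32.0), (680.0, 0.92, 28.0),
                   (1450.0, 0.38, 60.0), (1940.0, 0.52, 75.0)]),
]


def _continuum(wl: np.ndarray, plateau: float, red_edge: float) -> np.ndarray:
    """Smooth leaf-like continuum: dark visible, logistic red-edge rise to a
    NIR plateau, gentle SWIR decline."""
    vis = 0.04
    rise = 1.0 / (1.0 + np.exp(-(wl - red_edge) / 15.0))
    swir_decay = np.clip(1.0 - 0.25 * (wl - 1300.0) / 1100.0, 0.7, 1.0)
    return (vis + (plateau - vis) * rise) * swir_decay


def _species_base(wl: np.ndarray, params) -> np.ndarray:
    plateau, red_edge, feats = params
    base = _continuum(wl, plateau, red_edge)
    absorb = np.ones_like(wl)
    for center, depth, width in feats:
        # absorption features act below the red edge (pigments) or in SWIR
        # (water); each multiplies the continuum down locally
        absorb *= 1.0 - depth * np.exp(-0.5 * ((wl - center) / width) ** 2) * (
            0.55 if center < 700 else 0.85
        )
    return np.clip(base * absorb + 0.005, 0.0, 1.0)


def make_leaf_spectra(
    n_species: int = 3,
    n_individuals: int = 5,
    wavelengths: Optional[np.ndarray] = None,
    seed: int = 0,
    individual_sd: float = 0.04,
) -> LeafSpectraLibrary:
    """Generate a library of S·I labeled synthetic leaf spectra.

    Individuals perturb their species base spectrum with a smooth amplitude
    factor and per-feature depth jitter, both N(1, individual_sd) scaled.
    Deterministic for a given seed.
    """
    if n_species < 1 or n_individuals < 1:
        raise ParameterError("n_species and n_individuals must be >= 1")
    wl = DEFAULT_WAVELENGTHS if wavelengths is None else np.asarray(wavelengths, float)
    if wl.size < 10:
        raise ParameterError("need at least 10 wavelengths")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    spectra = []
    species_lab = []
    indiv_lab = []
    for s in range(n_species):
        params = _SPECIES_PARAMS[s % len(_SPECIES_PARAMS)]
        plateau, red_edge, feats = params
        if s >= len(_SPECIES_PARAMS):
            # extra species beyond the three archetypes: deterministic shifts
            plateau = min(0.65, plateau + 0.04 * (s // len(_SPECIES_PARAMS)))
            red_edge += 5.0 * (s // len(_SPECIES_PARAMS))
        for i in range(n_individuals):
            amp = 1.0 + individual_sd * rng.standard_normal()
            jfeats = [
                (c, d * max(0.2, 1.0 + individual_sd * rng.standard_normal()), w)
                for c, d, w in feats
            ]
            spec = _species_base(wl, (plateau * amp, red_edge, jfeats))
            spectra.append(np.clip(spec, 0.0, 1.0))
            species_lab.append(s)
            indiv_lab.append(i)
    return LeafSpectraLibrary(
        wavelengths=wl,
        spectra=np.asarray(spectra),
        species=np.asarray(species_lab),
        individual=np.asarray(indiv_lab),
        n_species=n_species,
        n_individuals=n_individuals,
    )


def assemble_high_beta(
    library: LeafSpectraLibrary,
    rows: int = 25,
    cols: int = 25,
    plot_px: int = 5,
    species_probs: Sequence[float] = DEFAULT_SPECIES_PROBS,
    seed: int = 0,
) -> LandscapeScenario:
    """Assemble the species-pure (high-β) landscape.

    One species is drawn per community from ``species_probs``; each pixel of
    the community gets the spectrum of an individual of that species drawn
    uniformly with replacement. Species-per-community and individual-per-pixel
    draws use separate substreams of the seed.
    """
    probs = np.asarray(species_probs, dtype=float)
    if probs.size != library.n_species:
        raise ParameterError(
            f"{probs.size} species probabilities for {library.n_species} species"
        )
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ParameterError(f"species probabilities sum to {probs.sum()}, not 1")
    if rows % plot_px or cols % plot_px:
        raise ParameterError(
            f"rows={rows}, cols={cols} must be divisible by plot_px={plot_px}"
        )
    q_rows, q_cols = rows // plot_px, cols // plot_px
    q = q_rows * q_cols
    rng_species = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    rng_indiv = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    comm_species = rng_species.choice(library.n_species, size=q, p=probs)

    pixel_species = np.empty((rows, cols), dtype=int)
    pixel_individual = np.empty((rows, cols), dtype=int)
    refl = np.empty((rows, cols, library.wavelengths.size))
    for k in range(q):
        r0 = (k // q_cols) * plot_px
        c0 = (k % q_cols) * plot_px
        s = comm_species[k]
        indiv = rng_indiv.integers(0, library.n_individuals, size=(plot_px, plot_px))
        pixel_species[r0:r0 + plot_px, c0:c0 + plot_px] = s
        pixel_individual[r0:r0 + plot_px, c0:c0 + plot_px] = indiv
        refl[r0:r0 + plot_px, c0:c0 + plot_px] = library.spectra[
            s * library.n_individuals + indiv
        ]
    cube = SpectralCube(reflectance=refl, wavelengths=library.wavelengths)
    grid, _, _ = make_community_grid(
        cube.valid_pixel_coords(), plot_px, (rows, cols)
    )
    return LandscapeScenario(
        cube=cube,
        pixel_species=pixel_species,
        pixel_individual=pixel_individual,
        grid=grid,
        scenario="high_beta",
        seed=seed,
    )


def permute_to_low_beta(
    scn: LandscapeScenario, seed: int = 0
) -> LandscapeScenario:
    """Shuffle pixel positions to collapse β while preserving γ exactly.

    Applies one uniform random permutation to the flattened pixel positions
    of the input landscape; the multiset of pixel spectra (hence SS_γ and
    SD_γ) is unchanged, while community memberships are randomized, so the
    among-community variance largely transfers to the within-community
    component. Grid geometry is kept as-is.
    """
    if scn.scenario != "high_beta":
        raise ValidationError("permute_to_low_beta expects a high_beta scenario")
    rows, cols = scn.cube.spatial_shape
    n = rows * cols
    perm = np.random.default_rng(np.random.SeedSequence([seed, 3])).permutation(n)
    flat = scn.cube.reflectance.reshape(n, -1)
    cube = scn.cube.with_reflectance(
        flat[perm].reshape(scn.cube.reflectance.shape)
    )
    return replace(
        scn,
        cube=cube,
        pixel_species=scn.pixel_species.reshape(n)[perm].reshape(rows, cols),
        pixel_individual=scn.pixel_individual.reshape(n)[perm].reshape(rows, cols),
        scenario="low_beta",
        seed=seed,
    )


def scenario_pair(
    seed: int = 0,
    rows: int = 25,
    cols: int = 25,
    plot_px: int = 5,
    n_species: int = 3,
    n_individuals: int = 5,
    species_probs: Sequence[float] = DEFAULT_SPECIES_PROBS,
    wavelengths: Optional[np.ndarray] = None,
    individual_sd: float = 0.06,
) -> Tuple[LandscapeScenario, LandscapeScenario]:
    """Convenience: build the matched (high-β, low-β) landscape pair."""
    lib = make_leaf_spectra(
        n_species, n_individuals, wavelengths, seed=seed,
        individual_sd=individual_sd,
    )
    high = assemble_high_beta(
        lib, rows=rows, cols=cols, plot_px=plot_px,
        species_probs=species_probs, seed=seed,
    )
    return high, permute_to_low_beta(high, seed=seed)
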