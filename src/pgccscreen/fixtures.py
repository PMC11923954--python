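"""Synthetic ground-truth data generators.

Two families of fixtures make every downstream stage testable without any
download or instrument:

* **Plate images** — 3-channel fluorescence wells (Hoechst / Calcein-AM /
  ethidium homodimer-1) with nuclei rendered as anti-aliased disks at known
  positions, sizes, viability and PGCC status.  PGCC nuclei are drawn with a
  radius a fixed ratio (default 2x, i.e. 4x area) above non-PGCC nuclei, well
  clear of the calling threshold.
* **Compound libraries** — tables of valid SMILES assembled from a small
  fragment grammar, pseudo-description text, and a response ``y`` computed
  from a planted structure-activity relationship (SAR) on the compound's own
  fingerprint.  A deterministic mock embedding provider stands in for a live
  text-embedding API and can mix the planted signal into the embeddings so
  description-based models are learnable on fixtures.

All randomness flows through an explicit integer seed per call; no global
RNG state is touched.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .imaging import SegmentationParams

__all__ = [
    "PlateGeometry",
    "ImageGroundTruth",
    "PlantedSAR",
    "generate_plate_image",
    "default_segmentation_params",
    "SMILES_FRAGMENTS",
    "generate_compound_library",
    "mock_embedding",
    "MockEmbeddingProvider",
    "EMBEDDING_DIMS",
]

#: Embedding dimensions of the two supported text-embedding model sizes.
EMBEDDING_DIMS: dict[str, int] = {"small": 1536, "large": 3072}


@dataclass(frozen=True)
class PlateGeometry:
    """Geometry and intensity configuration for synthetic well images.

    Non-PGCC nuclei get radii in ``nonpgcc_radius`` (pixels); PGCC nuclei are
    ``pgcc_radius_ratio`` times larger.  Intensities are 16-bit-like counts
    on a flat background with additive Gaussian noise.
    """

    shape: tuple[int, int] = (512, 512)
    nonpgcc_radius: tuple[float, float] = (6.0, 9.0)
    pgcc_radius_ratio: float = 2.0
    margin: float = 4.0  # extra pixels demanded between nucleus borders
    hoechst_amp: float = 10_000.0
    calcein_amp: float = 8_000.0
    ethidium_amp: float = 9_000.0
    background: float = 100.0
    noise_sd: float = 30.0
    max_retries: int = 2_000
    pixel_size: float = 0.65  # um per pixel (typical 20x widefield sampling)

    @property
    def pgcc_radius(self) -> tuple[float, float]:
        lo, hi = self.nonpgcc_radius
        return (lo * self.pgcc_radius_ratio, hi * self.pgcc_radius_ratio)


@dataclass
class Nucleus:
    center: tuple[float, float]  # (row, col)
    radius: float
    viability: Literal["live", "dead"]
    is_pgcc: bool


@dataclass
class ImageGroundTruth:
    """Known truth for one synthetic well."""

    well_id: str
    nuclei: list[Nucleus] = field(default_factory=list)
    pixel_size: float = 0.65

    @property
    def n_live(self) -> int:
        return sum(1 for n in self.nuclei if n.viability == "live")

    @property
    def n_dead(self) -> int:
        return sum(1 for n in self.nuclei if n.viability == "dead")

    @property
    def n_pgcc(self) -> int:
        return sum(1 for n in self.nuclei if n.viability == "live" and n.is_pgcc)

    @property
    def n_nonpgcc(self) -> int:
        return sum(1 for n in self.nuclei if n.viability == "live" and not n.is_pgcc)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "well": self.well_id,
                    "x": n.center[1],
                    "y": n.center[0],
                    "radius_px": n.radius,
                    "viability": n.viability,
                    "is_pgcc": n.is_pgcc,
                }
                for n in self.nuclei
            ],
            columns=["well", "x", "y", "radius_px", "viability", "is_pgcc"],
        )


class PlacementError(RuntimeError):
    """Raised when nuclei cannot be placed without overlap (image too crowded)."""


def _place_nuclei(
    specs: list[tuple[float, Literal["live", "dead"], bool]],
    geom: PlateGeometry,
    rng: np.random.Generator,
) -> list[Nucleus]:
    placed: list[Nucleus] = []
    h, w = geom.shape
    for radius, viability, is_pgcc in specs:
        ok = False
        for _ in range(geom.max_retries):
            r = rng.uniform(radius + geom.margin, h - radius - geom.margin)
            c = rng.uniform(radius + geom.margin, w - radius - geom.margin)
            if all(
                np.hypot(r - p.center[0], c - p.center[1])
                > radius + p.radius + geom.margin
                for p in placed
            ):
                placed.append(Nucleus((r, c), radius, viability, is_pgcc))
                ok = True
                break
        if not ok:
            raise PlacementError(
                f"could not place nucleus of radius {radius:.1f} after "
                f"{geom.max_retries} retries; image too crowded"
            )
    return placed


def _draw_disk(img: np.ndarray, center: tuple[float, float], radius: float, amp: float) -> None:
    """Add an anti-aliased filled disk: flat core, ~1 px soft edge."""
    r0, c0 = center
    rmin = max(int(np.floor(r0 - radius - 2)), 0)
    rmax = min(int(np.ceil(r0 + radius + 2)) + 1, img.shape[0])
    cmin = max(int(np.floor(c0 - radius - 2)), 0)
    cmax = min(int(np.ceil(c0 + radius + 2)) + 1, img.shape[1])
    rr, cc = np.mgrid[rmin:rmax, cmin:cmax]
    dist = np.hypot(rr - r0, cc - c0)
    profile = np.clip(radius - dist + 0.5, 0.0, 1.0)  # anti-aliased edge
    img[rmin:rmax, cmin:cmax] += amp * profile


def generate_plate_image(
    n_nonpgcc: int,
    n_pgcc: int,
    n_dead: int,
    seed: int,
    geom: PlateGeometry | None = None,
    well_id: str = "A01",
) -> tuple[np.ndarray, ImageGroundTruth]:
    """Render one synthetic well with known PGCC / non-PGCC / dead truth.

    Returns a float64 stack of shape (3, H, W) ordered (Hoechst, Calcein,
    ethidium) and the ground truth.  Every nucleus appears in the Hoechst
    channel; Calcein signal is drawn only at live nuclei and ethidium only at
    dead nuclei.  Dead nuclei are drawn at non-PGCC size.

    Raises :class:`PlacementError` if the requested nuclei cannot be placed
    without overlap.
    """
    if min(n_nonpgcc, n_pgcc, n_dead) < 0:
        raise ValueError("counts must be non-negative")
    geom = geom or PlateGeometry()
    rng = np.random.default_rng(seed)
    specs: list[tuple[float, Literal["live", "dead"], bool]] = []
    for _ in range(n_pgcc):  # place large nuclei first: easier packing
        specs.append((rng.uniform(*geom.pgcc_radius), "live", True))
    for _ in range(n_nonpgcc):
        specs.append((rng.uniform(*geom.nonpgcc_radius), "live", False))
    for _ in range(n_dead):
        specs.append((rng.uniform(*geom.nonpgcc_radius), "dead", False))
    nuclei = _place_nuclei(specs, geom, rng)

    stack = np.full((3, *geom.shape), geom.background, dtype=np.float64)
    for nuc in nuclei:
        _draw_disk(stack[0], nuc.center, nuc.radius, geom.hoechst_amp)
        if nuc.viability == "live":
            # calcein is cytoplasmic: a broader, dimmer footprint
            _draw_disk(stack[1], nuc.center, nuc.radius * 1.5, geom.calcein_amp)
        else:
            _draw_disk(stack[2], nuc.center, nuc.radius, geom.ethidium_amp)
    stack += rng.normal(0.0, geom.noise_sd, size=stack.shape)
    np.clip(stack, 0.0, None, out=stack)
    return stack, ImageGroundTruth(well_id=well_id, nuclei=nuclei, pixel_size=geom.pixel_size)


def default_segmentation_params(geom: PlateGeometry | None = None) -> SegmentationParams:
    """Segmentation parameters matched to :class:`PlateGeometry`.

    The PGCC area threshold is placed midway (on radius) between the largest
    non-PGCC and the smallest PGCC the generator can draw, so fixture truth
    is recovered exactly away from the decision boundary.
    """
    geom = geom or PlateGeometry()
    r_non_hi = geom.nonpgcc_radius[1]
    r_pgcc_lo = geom.pgcc_radius[0]
    r_cut = 0.5 * (r_non_hi + r_pgcc_lo)
    r_non_lo = geom.nonpgcc_radius[0]
    return SegmentationParams(
        min_area=0.25 * np.pi * r_non_lo**2,
        max_area=20.0 * np.pi * geom.pgcc_radius[1] ** 2,
        pgcc_area_threshold=float(np.pi * r_cut**2),
        dead_intensity_threshold=0.2 * geom.ethidium_amp,
        split_min_distance=max(3, int(r_non_lo)),
        pixel_size=geom.pixel_size,
    )


# --------------------------------------------------------------------------
# compound-library fixtures
# --------------------------------------------------------------------------

#: Chainable valid SMILES fragments.  Each fragment's first and last atom
#: tolerates one extra single bond, so any concatenation parses.
SMILES_FRAGMENTS: list[tuple[str, str]] = [
    ("C", "methyl"),
    ("CC", "ethylene"),
    ("CCC", "propylene"),
    ("CCCC", "butylene"),
    ("CO", "hydroxymethyl"),
    ("CCO", "ethanol-like"),
    ("COC", "methyl ether"),
    ("CN", "aminomethyl"),
    ("CCN", "ethylamine-like"),
    ("CNC", "methylamine bridge"),
    ("CSC", "thioether"),
    ("C=C", "vinylene"),
    ("CC(C)C", "isobutyl"),
    ("C(=O)N", "amide"),
    ("C(=O)O", "ester linkage"),
    ("c1ccccc1", "benzene ring"),
    ("c1ccncc1", "pyridine ring"),
    ("c1ccsc1", "thiophene ring"),
    ("C1CCCCC1", "cyclohexane ring"),
    ("C1CCNCC1", "piperidine ring"),
    ("C1CCOC1", "tetrahydrofuran ring"),
    ("c1ccc2ccccc2c1", "naphthalene system"),
]


@dataclass(frozen=True)
class PlantedSAR:
    """A planted linear structure-activity relationship.

    The synthetic response of a compound is
    ``y = intercept + w . fingerprint + Normal(0, noise_sd)`` where the
    fingerprint is computed on the compound's own SMILES with the named
    system.  Reproducible given the seed.
    """

    weights: np.ndarray
    system: str = "MACCS"
    intercept: float = 0.0
    noise_sd: float = 0.25
    seed: int = 0

    @classmethod
    def random(
        cls,
        system: str = "MACCS",
        n_nonzero: int = 12,
        scale: float = 0.6,
        noise_sd: float = 0.25,
        seed: int = 0,
    ) -> "PlantedSAR":
        """Sparse random weights over the system's bit positions."""
        from .features import FINGERPRINT_LENGTHS

        length = FINGERPRINT_LENGTHS[system]
        rng = np.random.default_rng(seed)
        w = np.zeros(length)
        idx = rng.choice(length, size=min(n_nonzero, length), replace=False)
        w[idx] = rng.normal(0.0, scale, size=idx.size)
        return cls(weights=w, system=system, noise_sd=noise_sd, seed=seed)


def generate_compound_library(
    n: int,
    sar: PlantedSAR,
    seed: int,
    fragments_per_compound: tuple[int, int] = (2, 5),
) -> pd.DataFrame:
    """Generate ``n`` synthetic compounds with SMILES, descriptions and y.

    SMILES are concatenations of fragments from :data:`SMILES_FRAGMENTS`
    (always valid by construction; each is verified through the parser).
    The response column ``y_true`` follows the planted SAR evaluated on each
    compound's own fingerprint.  Identical ``(n, sar, seed)`` reproduce the
    table bit-exactly.
    """
    from rdkit import Chem

    from .features import compute_fingerprint

    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = fragments_per_compound
    if not (1 <= lo <= hi):
        raise ValueError("invalid fragments_per_compound range")
    rng = np.random.default_rng(seed)
    noise_rng = np.random.default_rng(sar.seed + 1)
    rows = []
    for i in range(n):
        k = int(rng.integers(lo, hi + 1))
        picks = rng.integers(0, len(SMILES_FRAGMENTS), size=k)
        smiles = "".join(SMILES_FRAGMENTS[j][0] for j in picks)
        if Chem.MolFromSmiles(smiles) is None:  # pragma: no cover - grammar is safe
            raise ValueError(f"fragment grammar produced invalid SMILES: {smiles}")
        names = [SMILES_FRAGMENTS[j][1] for j in picks]
        description = (
            f"Synthetic screening compound CPD{i:05d} built from "
            + ", ".join(names)
            + " moieties."
        )
        fp = compute_fingerprint(smiles, sar.system).bits
        y = sar.intercept + float(np.dot(sar.weights, fp))
        if sar.noise_sd > 0:
            y += float(noise_rng.normal(0.0, sar.noise_sd))
        rows.append(
            {
                "compound_id": f"CPD{i:05d}",
                "smiles": smiles,
                "description": description,
                "y_true": y,
            }
        )
    return pd.DataFrame(rows)


def _text_seed(text: str, seed: int) -> np.random.Generator:
    digest = hashlib.blake2b(text.encode(), digest_size=8).digest()
    return np.random.default_rng(
        [int.from_bytes(digest[:4], "little"), int.from_bytes(digest[4:], "little"), seed]
    )


def mock_embedding(
    description: str,
    dim: int,
    seed: int = 0,
    signal: float | None = None,
    signal_strength: float = 1.0,
) -> np.ndarray:
    """Deterministic stand-in for a text-embedding API call.

    The vector is hash-seeded from the text, so identical inputs always give
    identical vectors.  ``dim`` must be 1536 or 3072 (the two supported
    embedding sizes).  When ``signal`` is given, the first coordinate carries
    ``signal * signal_strength`` plus the hash noise, letting models trained
    on embeddings learn a planted response.
    """
    if dim not in EMBEDDING_DIMS.values():
        raise ValueError(f"unsupported embedding dim {dim}; expected 1536 or 3072")
    rng = _text_seed(description, seed)
    vec = rng.standard_normal(dim)
    if signal is not None:
        vec[0] += signal * signal_strength
    return vec


class MockEmbeddingProvider:
    """Deterministic embedding provider satisfying the provider interface.

    ``signal_map`` optionally maps description text to a planted scalar mixed
    into the embedding (see :func:`mock_embedding`).
    """

    def __init__(
        self,
        seed: int = 0,
        signal_map: dict[str, float] | None = None,
        signal_strength: float = 1.0,
    ) -> None:
        self.seed = seed
        self.signal_map = signal_map or {}
        self.signal_strength = signal_strength

    def embed(self, text: str, model: str = "small") -> np.ndarray:
        dim = EMBEDDING_DIMS.get(model)
        if dim is None:
            raise ValueError(f"unknown embedding model {model!r}")
        return mock_embedding(
            text,
            dim,
            seed=self.seed,
            signal=self.signal_map.get(text),
            signal_strength=self.signal_strength,
        )
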