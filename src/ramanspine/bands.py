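"""Vibrational band assignments for vertebral tissues.

The six tissue classes measured around a porcine vertebra (bone, cartilage,
fat, ligament, muscle, spinal cord) each carry a characteristic set of
narrow Raman bands in the fingerprint region.  The table below records, for
every band, its center (or center range), the vibrational mode, the
biomolecular assignment, and an ordinal 0-4 relative-concentration score
per tissue (0 meaning the band is not visually detectable in that tissue).
Cartilage and ligament share one "connective" column, as is usual in
tissue band compilations; the generator separates them with small
documented perturbations (see :data:`CONNECTIVE_TWEAKS`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

TISSUES = ("bone", "cartilage", "fat", "ligament", "muscle", "spinal_cord")

MAX_BAND_FWHM = 50.0  # Raman bands in tissue are narrow, < 50 cm^-1


@dataclass(frozen=True)
class Band:
    """One Raman band: center in cm^-1, FWHM in cm^-1, ordinal star scores."""

    center: float
    low: float
    high: float
    mode: str
    assignment: str
    stars: dict[str, int] = field(default_factory=dict)
    width: float = 12.0
    # center a reader would quote for this band (printed value where one
    # exists, e.g. 961 for the mineral band; otherwise the range midpoint)
    representative: float = 0.0

    def __post_init__(self) -> None:
        if self.width >= MAX_BAND_FWHM:
            raise ValueError(f"band FWHM {self.width} exceeds {MAX_BAND_FWHM} cm^-1")
        for tissue, s in self.stars.items():
            if s not in (0, 1, 2, 3, 4):
                raise ValueError(f"star score {s} for {tissue} outside 0-4")
        if self.representative == 0.0:
            object.__setattr__(self, "representative", self.center)


def _band(low, high, mode, assignment, muscle, connective, cord, fat, bone,
          representative=0.0, width=12.0):
    center = (low + high) / 2.0
    stars = {
        "muscle": muscle,
        "cartilage": connective,
        "ligament": connective,
        "fat": fat,
        "bone": bone,
        "spinal_cord": cord,
    }
    return Band(center=center, low=low, high=high, mode=mode,
                assignment=assignment, stars=stars, width=width,
                representative=representative)


#: Ordinal band-intensity table for the six tissues.  Star scores run 0-4
#: (columns: muscle, connective, spinal cord, fat, bone); the connective
#: score is copied to both cartilage and ligament.
BAND_TABLE: tuple[Band, ...] = (
    _band(817, 817, "C-C stretching", "collagen", 0, 4, 0, 0, 0),
    _band(857, 857, "C-C vibration", "collagen backbone hydroxyproline", 3, 4, 0, 0, 0),
    _band(943, 945, "C-C stretching", "protein backbone", 3, 4, 0, 0, 0),
    _band(959, 965, "calcium-phosphate stretch", "calcium hydroxyapatite",
          0, 3, 0, 0, 4, representative=961.0),
    _band(1005, 1005, "symmetric ring breathing", "phenylalanine", 3, 4, 0, 0, 0),
    _band(1067, 1069, "nu(C-O)", "proline, collagen", 1, 4, 3, 2, 0),
    _band(1081, 1083, "C-N stretching", "proteins, lipids", 1, 4, 3, 2, 0),
    _band(1131, 1131, "C-C skeletal stretching", "palmitic and fatty acids", 4, 3, 2, 0, 0),
    _band(1249, 1249, "C-N stretching", "amide III", 4, 0, 3, 0, 0),
    _band(1269, 1271, "C-H, delta(=C-H)", "amide III, lipids, phospholipids", 0, 4, 0, 3, 0),
    _band(1305, 1305, "CH3/CH2 twisting", "collagen", 2, 1, 3, 4, 0),
    _band(1325, 1325, "CH3CH2 wagging", "nucleic acids", 4, 3, 0, 0, 0),
    _band(1344, 1344, "delta(CH)", "amide III", 3, 4, 0, 0, 0),
    _band(1439, 1442, "CH2/CH3 deformation", "DNA/RNA, protein (amide I), lipids",
          1, 2, 4, 3, 0, representative=1441.0),
    _band(1448, 1451, "CH2CH3 deformation", "collagen, lipids, proteins", 4, 3, 2, 1, 0),
    _band(1641, 1641, "delta(HOH)", "water", 0, 4, 0, 0, 0),
    _band(1658, 1665, "nu-helix", "amide I", 4, 3, 1, 2, 0),
)

#: Multiplicative per-band corrections splitting the shared connective
#: column into distinct cartilage and ligament signatures.  Cartilage's
#: 1448-1451 cm^-1 band is weak relative to ligament, while the connective
#: mineral (hydroxyapatite, 959-965 cm^-1) deposits occur in articular
#: cartilage rather than ligament.  Keys are band centers in cm^-1.
CONNECTIVE_TWEAKS: dict[str, dict[float, float]] = {
    "cartilage": {1449.5: 0.35},
    "ligament": {962.0: 0.25},
}


def find_band(wavenumber: float, table: tuple[Band, ...] = BAND_TABLE) -> Band:
    """Return the table band whose region lies closest to *wavenumber*.

    Distance to a band is zero inside [low - width/2, high + width/2] and
    the gap to the nearest edge outside it.
    """
    def dist(b: Band) -> float:
        lo, hi = b.low - b.width / 2, b.high + b.width / 2
        if lo <= wavenumber <= hi:
            return 0.0
        return min(abs(wavenumber - lo), abs(wavenumber - hi))

    return min(table, key=dist)
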