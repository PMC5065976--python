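"""DC tissue conductivity catalogue.

Conductivities are DC (low-frequency, ~10 Hz) values in S/m assigned per
tissue, as used in quasi-static volume-conductor models of transcutaneous DC
stimulation.  The catalogue also carries the two electrode materials (metal
pad, saline sponge) and a handful of structural labels (occipital cortex,
cauda equina, arm stub) that share the conductivity of their parent tissue
class but are tracked separately so exposure statistics can be reported per
structure.

Tissue IDs are stable small integers assigned from the ordered manifest below;
ID 0 is reserved for exterior air (the bounding box surrounding the body).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "TissueCatalogue",
    "default_catalogue",
    "lookup_conductivity",
    "EXTERIOR_AIR",
    "PAD",
    "SPONGE",
]

EXTERIOR_AIR = "Exterior air"
PAD = "Electrode pad"
SPONGE = "Electrode sponge"

# Ordered manifest: (name, sigma in S/m).  Order defines the integer tissue ID
# (index in this tuple), so files written with one version of the package read
# back identically.  Exterior air must stay first (ID 0).
_MANIFEST: tuple[tuple[str, float], ...] = (
    (EXTERIOR_AIR, 0.0),
    ("Adrenal gland", 0.511),
    ("Epididymis", 0.511),
    ("Esophagus", 0.511),
    ("Hypophysis", 0.511),
    ("Pancreas", 0.511),
    ("Pineal body", 0.511),
    ("Small intestine", 0.511),
    ("Small intestine lumen", 0.511),
    ("Stomach", 0.511),
    ("Stomach lumen", 0.511),
    ("Thymus", 0.511),
    ("Thyroid gland", 0.511),
    ("Air internal", 0.0),
    ("Bronchi lumen", 0.0),
    ("Pharynx", 0.0),
    ("Trachea lumen", 0.0),
    ("Artery", 0.7),
    ("Blood vessels", 0.7),
    ("Hearth lumen", 0.7),
    ("Penis", 0.7),
    ("Vein", 0.7),
    ("Bladder", 0.203),
    ("Bone", 0.0200),
    ("Mandible", 0.0200),
    ("Marrow red", 0.0200),
    ("Skull", 0.0200),
    ("Teeth", 0.0200),
    ("Vertebrae", 0.0200),
    ("Brain gray matter", 0.0275),
    ("Hippocampus", 0.0275),
    ("Hypothalamus", 0.0275),
    ("Thalamus", 0.0275),
    ("Brain white matter", 0.0277),
    ("Commissura anterior", 0.0277),
    ("Commissura posterior", 0.0277),
    ("Breast", 0.262),
    ("Bronchi", 0.251),
    ("Ureter-urethra", 0.251),
    ("Cartilage", 0.161),
    ("Ear cartilage", 0.161),
    ("Intervertebral disks", 0.161),
    ("Larynx", 0.161),
    ("Trachea", 0.161),
    ("Cerebellum", 0.0475),
    ("Cerebro spinal fluid (CSF)", 2.0),
    ("Connective tissue", 0.122),
    ("Cornea", 0.411),
    ("Prostate", 0.411),
    ("Testis", 0.411),
    ("Diaphragm", 0.202),
    ("Muscle", 0.202),
    ("Ear skin", 0.1),
    ("Skin", 0.1),
    ("Eye lens", 0.311),
    ("Ovary", 0.311),
    ("Eye sclera", 0.501),
    ("Eye vitreous humor", 1.5),
    ("Fat", 0.0122),
    ("Subcutaneous adipose tissue (SAT)", 0.0122),
    ("Gallbladder", 0.9),
    ("Hearth muscle", 0.0537),
    ("Kidney cortex", 0.0544),
    ("Kidney medulla", 0.0544),
    ("Large intestine", 0.0122),
    ("Large intestine lumen", 0.0122),
    ("Vagina", 0.0122),
    ("Liver", 0.0277),
    ("Lung", 0.121),
    ("Medulla oblongata", 0.0276),
    ("Midbrain", 0.0276),
    ("Pons", 0.0276),
    ("Mucosa", 0.0004),
    ("Nerve", 0.0171),
    ("Spinal cord", 0.0171),
    ("Spleen", 0.0396),
    ("Tendon ligament", 0.251),
    ("Tongue", 0.261),
    ("Uterus", 0.201),
    # Electrode materials: metallic pad over a saline-soaked sponge.
    (PAD, 5.9e7),
    (SPONGE, 0.3),
    # Structural labels sharing a parent tissue class conductivity, kept
    # distinct so per-structure exposure statistics can be reported.
    ("Occipital cortex", 0.0275),       # gray matter
    ("Cauda equina", 0.0171),           # nerve
    ("Spinal cord cervical", 0.0171),
    ("Spinal cord thoracic", 0.0171),
    ("Spinal cord lumbar", 0.0171),
    ("Spinal cord sacral", 0.0171),
    ("Arm stub", 0.202),                # muscle-equivalent return path
)

# Common alternate spellings accepted by lookup (case-folded).
_ALIASES: dict[str, str] = {
    "heart muscle": "Hearth muscle",
    "heart lumen": "Hearth lumen",
    "csf": "Cerebro spinal fluid (CSF)",
    "cerebrospinal fluid": "Cerebro spinal fluid (CSF)",
    "gray matter": "Brain gray matter",
    "white matter": "Brain white matter",
}


class UnknownTissueError(KeyError):
    """Raised when a tissue name does not resolve in the catalogue."""


@dataclass(frozen=True)
class TissueCatalogue:
    """Immutable map from tissue name to DC conductivity (S/m).

    Attributes
    ----------
    entries :
        Mapping tissue-name -> conductivity in S/m.  Names are unique after
        case-folding; all conductivities are >= 0.
    """

    entries: dict[str, float]
    _folded: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        folded: dict[str, str] = {}
        for name, sigma in self.entries.items():
            key = name.casefold()
            if key in folded:
                raise ValueError(f"duplicate tissue name after case-folding: {name!r}")
            if sigma < 0:
                raise ValueError(f"negative conductivity for {name!r}: {sigma}")
            folded[key] = name
        object.__setattr__(self, "_folded", folded)

    def resolve(self, name: str) -> str:
        """Return the canonical catalogue name for ``name`` (case-insensitive)."""
        key = name.casefold()
        if key in self._folded:
            return self._folded[key]
        if key in _ALIASES:
            return _ALIASES[key]
        raise UnknownTissueError(f"unknown tissue: {name!r}")

    def conductivity(self, name: str) -> float:
        return self.entries[self.resolve(name)]

    def __contains__(self, name: str) -> bool:
        try:
            self.resolve(name)
        except UnknownTissueError:
            return False
        return True

    # --- stable integer IDs -------------------------------------------------

    def tissue_id(self, name: str) -> int:
        return self._ids[self.resolve(name)]

    def tissue_name(self, tid: int) -> str:
        return self._names[tid]

    @property
    def _ids(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.entries)}

    @property
    def _names(self) -> dict[int, str]:
        return {i: name for i, name in enumerate(self.entries)}

    def id_map(self) -> dict[int, str]:
        """Integer ID -> tissue name, for sidecar metadata files."""
        return dict(self._names)

    def sigma_by_id(self) -> dict[int, float]:
        return {i: sigma for i, sigma in enumerate(self.entries.values())}


_DEFAULT: TissueCatalogue | None = None


def default_catalogue() -> TissueCatalogue:
    """The package's standard catalogue (tissues + electrode materials)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = TissueCatalogue(entries=dict(_MANIFEST))
    return _DEFAULT


def lookup_conductivity(catalogue: TissueCatalogue, name: str) -> float:
    """DC conductivity (S/m) of ``name``, case-insensitive.

    Raises
    ------
    UnknownTissueError
        If the name does not resolve, naming the missing entry.
    """
    return catalogue.conductivity(name)
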