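"""Class scheme for glioma tile classification.

The five-way tissue scheme used throughout the package: the three adult-type
diffuse glioma subtypes of the 2021 WHO CNS classification — astrocytoma
(IDH-mutant, ``ac``), oligodendroglioma (IDH-mutant 1p/19q-codeleted, ``odg``)
and glioblastoma (IDH-wildtype, ``gbm``) — plus normal brain tissue and
necrosis.  The scheme also encodes the slide-level consistency rule: a slide
carries a single patient diagnosis, and only the diagnosed tumor subtype,
normal tissue and necrosis can occur on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ClassScheme:
    """Ordered tissue classes, the tumor partition and the diagnosis rule.

    Parameters
    ----------
    labels
        Ordered class identifiers.  The order is the canonical class order
        used for probability vectors, confusion matrices and argmax
        tie-breaking.
    tumor_labels
        Subset of ``labels`` regarded as tumor classes (the glioma subtypes).
    normal_label, necrosis_label
        The two non-tumor classes.  ``normal_label`` doubles as the diagnosis
        identifier of non-cancer control slides.

    Notes
    -----
    For a tumor diagnosis ``d`` the permitted tile classes are
    ``{d, normal, necrosis}``.  For the normal-control diagnosis they are
    ``{normal}`` only: whether control slides may contain necrotic regions is
    not defined by the diagnosis rule itself, and this package takes the
    strict reading (a non-cancer control contains no necrosis).
    """

    labels: tuple[str, ...] = ("ac", "odg", "gbm", "normal", "necrosis")
    tumor_labels: frozenset[str] = frozenset({"ac", "odg", "gbm"})
    normal_label: str = "normal"
    necrosis_label: str = "necrosis"

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError(f"duplicate class labels: {self.labels}")
        object.__setattr__(self, "tumor_labels", frozenset(self.tumor_labels))
        unknown = self.tumor_labels - set(self.labels)
        if unknown:
            raise ValueError(f"tumor_labels not in labels: {sorted(unknown)}")
        for name in (self.normal_label, self.necrosis_label):
            if name not in self.labels:
                raise ValueError(f"label {name!r} missing from labels")
            if name in self.tumor_labels:
                raise ValueError(f"non-tumor label {name!r} listed as tumor")

    @property
    def n_classes(self) -> int:
        return len(self.labels)

    @property
    def diagnoses(self) -> tuple[str, ...]:
        """Valid slide diagnoses: every tumor subtype plus the normal control."""
        return tuple(c for c in self.labels if c in self.tumor_labels) + (
            self.normal_label,
        )

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown class label {label!r}") from None

    def allowed_classes(self, diagnosis: str) -> frozenset[str]:
        """Tile classes permitted on a slide with the given diagnosis."""
        if diagnosis in self.tumor_labels:
            return frozenset({diagnosis, self.normal_label, self.necrosis_label})
        if diagnosis == self.normal_label:
            return frozenset({self.normal_label})
        raise KeyError(f"unknown diagnosis {diagnosis!r}")


#: Default five-class scheme shared by the whole package.
DEFAULT_SCHEME = ClassScheme()
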