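"""Symbolic model structure: which terms enter which parameter family.

A :class:`ModelSpec` assigns an ordered list of :class:`Term` objects to
each parameter family (``psi``, ``theta``, ``theta_prime``, ``gamma``,
``epsilon``, ``p1``, ``p2``, ``pi_mix``). Each term contributes exactly
one coefficient on the log-odds scale, so the total parameter count is
the total number of terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

FAMILIES = ("psi", "theta", "theta_prime", "gamma", "epsilon", "p1", "p2", "pi_mix")

#: Covariate components resolvable from a covariate table.
COMPONENTS = ("mean", "deviation", "first_year", "raw")


@dataclass(frozen=True)
class Term:
    """One design column: intercept, covariate component, year dummy or stop power."""

    kind: str  # "intercept" | "covariate" | "year_dummy" | "stop_poly"
    name: str | None = None  # covariate name (kind == "covariate")
    component: str | None = None  # mean | deviation | first_year | raw
    year: int | None = None  # kind == "year_dummy"
    degree: int | None = None  # kind == "stop_poly"

    def __post_init__(self) -> None:
        if self.kind not in ("intercept", "covariate", "year_dummy", "stop_poly"):
            raise ValueError(f"unknown term kind {self.kind!r}")
        if self.kind == "covariate":
            if not self.name:
                raise ValueError("covariate term needs a name")
            if self.component not in COMPONENTS:
                raise ValueError(f"unknown covariate component {self.component!r}")
        if self.kind == "year_dummy" and self.year is None:
            raise ValueError("year_dummy term needs a year")
        if self.kind == "stop_poly" and (self.degree is None or self.degree < 1):
            raise ValueError("stop_poly term needs degree >= 1")

    @property
    def label(self) -> str:
        if self.kind == "intercept":
            return "intercept"
        if self.kind == "covariate":
            return f"{self.name}_{self.component}"
        if self.kind == "year_dummy":
            return f"year_{self.year}"
        return f"stop^{self.degree}"


def intercept() -> Term:
    return Term("intercept")


def covariate(name: str, component: str = "raw") -> Term:
    return Term("covariate", name=name, component=component)


def year_dummies(years) -> list[Term]:
    """One dummy per year; the baseline year is whichever is omitted."""
    return [Term("year_dummy", year=int(y)) for y in years]


def stop_poly(degree: int) -> list[Term]:
    """Polynomial in standardized stop number, one term per power 1..degree."""
    return [Term("stop_poly", degree=d) for d in range(1, degree + 1)]


@dataclass(frozen=True)
class ModelSpec:
    """Ordered term lists per parameter family, each with an intercept first."""

    psi: tuple[Term, ...]
    theta: tuple[Term, ...]
    theta_prime: tuple[Term, ...]
    gamma: tuple[Term, ...]
    epsilon: tuple[Term, ...]
    p1: tuple[Term, ...]
    p2: tuple[Term, ...]
    pi_mix: tuple[Term, ...] = field(default_factory=lambda: (intercept(),))

    def __post_init__(self) -> None:
        for fam in FAMILIES:
            terms = tuple(getattr(self, fam))
            object.__setattr__(self, fam, terms)
            if not terms or terms[0].kind != "intercept":
                raise ValueError(f"family {fam} must start with an intercept term")
            if len(set(terms)) != len(terms):
                raise ValueError(f"family {fam} contains duplicate terms")

    def terms(self, family: str) -> tuple[Term, ...]:
        if family not in FAMILIES:
            raise KeyError(family)
        return getattr(self, family)

    def with_family(self, family: str, terms) -> "ModelSpec":
        return replace(self, **{family: tuple(terms)})

    def drop_term(self, family: str, term: Term) -> "ModelSpec":
        kept = tuple(t for t in self.terms(family) if t != term)
        if len(kept) == len(self.terms(family)):
            raise ValueError(f"term {term.label} not present in family {family}")
        return self.with_family(family, kept)

    def family_sizes(self) -> dict[str, int]:
        return {fam: len(self.terms(fam)) for fam in FAMILIES}


def count_parameters(spec: ModelSpec) -> int:
    """Total coefficient count: the sum of term counts over all families."""
    return sum(spec.family_sizes().values())


def global_spec(
    years,
    covariate_names: dict[str, list[str]] | None = None,
    detection_stop_degree: int = 2,
) -> ModelSpec:
    """The most general model structure used as a starting point.

    ``years`` is the ordered survey-year grid. ``covariate_names`` maps
    ``"habitat"`` and ``"climate"`` to covariate base names (habitat: one
    name; climate: typically heat and cold stress). Initial occupancy
    and availability get the spatial means of every covariate;
    colonization/extinction get year dummies (baseline: the first
    transition) plus the spatial means; detection gets year dummies
    (baseline: the first year) plus a stop polynomial, separately per
    mixture class.
    """
    years = [int(y) for y in years]
    if covariate_names is None:
        covariate_names = {"habitat": ["habitat"], "climate": ["heat", "cold"]}
    all_names = list(covariate_names.get("habitat", [])) + list(
        covariate_names.get("climate", [])
    )
    means = [covariate(n, "mean") for n in all_names]
    psi_terms = [intercept()] + [covariate(n, "first_year") for n in all_names]
    vital = [intercept()] + year_dummies(years[2:]) + means
    det = (
        [intercept()]
        + year_dummies(years[1:])
        + stop_poly(detection_stop_degree)
    )
    return ModelSpec(
        psi=tuple(psi_terms),
        theta=tuple([intercept()] + means),
        theta_prime=tuple([intercept()] + means),
        gamma=tuple(vital),
        epsilon=tuple(vital),
        p1=tuple(det),
        p2=tuple(det),
        pi_mix=(intercept(),),
    )
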