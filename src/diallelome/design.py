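"""Full reciprocal diallel mating designs.

A full reciprocal diallel crosses every parent with every other parent in
both directions (mother x father and father x mother) without selfs, so
``p`` parents yield ``p * (p - 1)`` hybrids.  Each genotype (inbred parent
or hybrid) is grown in ``n_replicates`` biological replicates, and samples
are measured in ``n_batches`` batches.
"""

from __future__ import annotations

from dataclasses import dataclass, replace


def hybrid_id(mother: str, father: str) -> str:
    """Canonical identifier of the ordered cross mother x father."""
    return f"{mother}x{father}"


@dataclass(frozen=True)
class DiallelDesign:
    """Parents, ordered hybrid pairs and replicate structure of a diallel.

    Attributes
    ----------
    parents:
        Ordered parent identifiers.
    hybrids:
        Every ordered pair ``(mother, father)`` of distinct parents,
        mothers in parent order, then fathers.
    n_replicates:
        Biological replicates per genotype (>= 2, required for variance
        estimation).
    n_batches:
        Number of measurement batches.
    """

    parents: tuple[str, ...]
    hybrids: tuple[tuple[str, str], ...]
    n_replicates: int
    n_batches: int

    @property
    def hybrid_ids(self) -> tuple[str, ...]:
        return tuple(hybrid_id(m, f) for m, f in self.hybrids)

    @property
    def genotypes(self) -> tuple[str, ...]:
        """All genotype identifiers: parents first, then hybrids."""
        return self.parents + self.hybrid_ids

    @property
    def n_samples(self) -> int:
        return len(self.genotypes) * self.n_replicates

    def parents_of(self, hyb: str) -> tuple[str, str]:
        """(mother, father) of a hybrid identifier."""
        for m, f in self.hybrids:
            if hybrid_id(m, f) == hyb:
                return m, f
        raise KeyError(f"unknown hybrid {hyb!r}")

    def drop_hybrid(self, hyb: str) -> "DiallelDesign":
        """Design with one hybrid removed (for leave-one-hybrid-out runs)."""
        kept = tuple(p for p in self.hybrids if hybrid_id(*p) != hyb)
        if len(kept) == len(self.hybrids):
            raise KeyError(f"unknown hybrid {hyb!r}")
        return replace(self, hybrids=kept)


def make_design(
    parent_ids: list[str] | tuple[str, ...],
    n_replicates: int = 6,
    n_batches: int = 3,
) -> DiallelDesign:
    """Build a full reciprocal diallel design.

    Parameters
    ----------
    parent_ids:
        At least two distinct parent identifiers.
    n_replicates:
        Biological replicates per genotype; must be >= 2 so that
        within-group variances are estimable.
    n_batches:
        Number of measurement batches (>= 1).

    Returns
    -------
    DiallelDesign
        With ``p * (p - 1)`` hybrids in deterministic order (mothers in
        parent order, then fathers).
    """
    parents = tuple(str(p) for p in parent_ids)
    if len(parents) < 2:
        raise ValueError("need at least two parents for a diallel")
    if len(set(parents)) != len(parents):
        dupes = sorted({p for p in parents if list(parents).count(p) > 1})
        raise ValueError(f"duplicate parent ids: {dupes}")
    if n_replicates < 2:
        raise ValueError(
            "n_replicates must be >= 2 (within-genotype variance estimation "
            "is impossible with a single replicate)"
        )
    if n_batches < 1:
        raise ValueError("n_batches must be >= 1")
    hybrids = tuple(
        (mother, father)
        for mother in parents
        for father in parents
        if father != mother
    )
    return DiallelDesign(
        parents=parents,
        hybrids=hybrids,
        n_replicates=int(n_replicates),
        n_batches=int(n_batches),
    )
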