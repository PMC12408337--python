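"""Partial charges from refined ionic fractions; merging and comparison.

The partial charge of an atom is delta_q = nu * dZ (electrons), with
esu(delta_q) = |dZ| * esu(nu) propagated from the refinement covariance.
Charges from replicate datasets of the same structure are combined as the
inverse-variance weighted mean.  Agreement with reference charge sets
(quantum-chemical tables read from two-column files) is quantified by the
Pearson correlation coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class ChargeEntry:
    label: str
    element: str = ""
    dZ: int = 0
    nu: float = 0.0
    dq: float = 0.0
    esu: float = 0.0
    fixed: bool = False

    def __post_init__(self):
        if self.esu < 0:
            raise ValueError("esu must be non-negative")


@dataclass
class ChargeSet:
    entries: list[ChargeEntry]
    provenance: str = ""

    def __post_init__(self):
        labels = [e.label for e in self.entries]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate atom labels in charge set")

    def __len__(self):
        return len(self.entries)

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.entries]

    def entry(self, label: str) -> ChargeEntry:
        for e in self.entries:
            if e.label == label:
                return e
        raise KeyError(f"no charge entry for {label!r}")

    def value(self, label: str) -> float:
        return self.entry(label).dq

    def esu(self, label: str) -> float:
        return self.entry(label).esu

    def total(self) -> float:
        return float(sum(e.dq for e in self.entries))

    def subset(self, include_hydrogens: bool = True) -> "ChargeSet":
        kept = [e for e in self.entries
                if include_hydrogens or e.element.capitalize() != "H"]
        return ChargeSet(kept, provenance=self.provenance)

    def as_table(self) -> str:
        """Delimiter-separated charge report."""
        lines = ["label\telement\tdZ\tnu\tdq\tesu\tflags"]
        for e in self.entries:
            flag = "fixed" if e.fixed else ""
            lines.append(f"{e.label}\t{e.element}\t{e.dZ}\t{e.nu:.5f}\t"
                         f"{e.dq:.5f}\t{e.esu:.5f}\t{flag}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_table(cls, text: str, provenance: str = "") -> "ChargeSet":
        entries = []
        for i, line in enumerate(text.strip().splitlines()):
            if i == 0 and line.startswith("label"):
                continue
            parts = line.split("\t")
            entries.append(ChargeEntry(
                label=parts[0], element=parts[1], dZ=int(parts[2]),
                nu=float(parts[3]), dq=float(parts[4]), esu=float(parts[5]),
                fixed=(len(parts) > 6 and parts[6] == "fixed")))
        return cls(entries, provenance=provenance)


def extract_charges(result, model, provenance: str = "",
                    force: bool = False) -> ChargeSet:
    """delta_q = nu * dZ per atom from a refinement result; fixed-neutral
    sites are reported as exactly zero with zero esu and a flag."""
    if not result.converged and not force:
        raise RuntimeError("refinement did not converge; pass force=True "
                           "to extract charges anyway")
    entries = []
    for site in model.sites:
        if site.nu_fixed:
            entries.append(ChargeEntry(
                label=site.label, element=site.ion.element, dZ=site.ion.dZ,
                nu=site.nu, dq=site.nu * site.ion.dZ, esu=0.0, fixed=True))
        else:
            nu = result.nu(site.label)
            esu_nu = result.nu_esd(site.label)
            entries.append(ChargeEntry(
                label=site.label, element=site.ion.element, dZ=site.ion.dZ,
                nu=nu, dq=nu * site.ion.dZ, esu=abs(site.ion.dZ) * esu_nu))
    return ChargeSet(entries, provenance=provenance)


def combine_datasets(sets: list[ChargeSet]) -> ChargeSet:
    """Inverse-variance weighted mean per label over the contributing sets;
    labels missing in some sets are combined over the available ones."""
    if not sets:
        raise ValueError("need at least one charge set")
    if len(sets) == 1:
        return ChargeSet([ChargeEntry(**e.__dict__) for e in sets[0].entries],
                         provenance=sets[0].provenance)
    all_labels = []
    for cs in sets:
        for e in cs.entries:
            if e.label not in all_labels:
                all_labels.append(e.label)
    merged = []
    coverage_notes = []
    for label in all_labels:
        hits = [cs.entry(label) for cs in sets if label in cs.labels]
        if len(hits) < len(sets):
            coverage_notes.append(f"{label}:{len(hits)}/{len(sets)}")
        zero_esu = [h for h in hits if h.esu == 0]
        if zero_esu:
            vals = {round(h.dq, 12) for h in hits}
            if len(vals) > 1:
                raise ValueError(
                    f"label {label!r} has an exact (esu=0) value conflicting "
                    "with other datasets")
            ref = hits[0]
            merged.append(ChargeEntry(label=label, element=ref.element,
                                      dZ=ref.dZ, nu=ref.nu, dq=ref.dq,
                                      esu=0.0, fixed=ref.fixed))
            continue
        w = np.array([1.0 / h.esu**2 for h in hits])
        q = np.array([h.dq for h in hits])
        qbar = float(np.sum(w * q) / np.sum(w))
        sbar = float(1.0 / np.sqrt(np.sum(w)))
        ref = hits[0]
        nu_bar = qbar / ref.dZ if ref.dZ != 0 else 0.0
        merged.append(ChargeEntry(label=label, element=ref.element, dZ=ref.dZ,
                                  nu=nu_bar, dq=qbar, esu=sbar))
    prov = "+".join(cs.provenance for cs in sets if cs.provenance)
    if coverage_notes:
        prov += " [coverage " + ",".join(coverage_notes) + "]"
    return ChargeSet(merged, provenance=prov)


def group_charge(charge_set: ChargeSet, labels: list[str],
                 covariance: np.ndarray | None = None,
                 cov_labels: list[str] | None = None) -> tuple[float, float]:
    """Total charge of a functional group with propagated esu.

    With the full delta_q covariance block (ordered as ``cov_labels``), the
    esu is sqrt(1' C 1); otherwise independent-sum propagation is used.
    """
    if not labels:
        return 0.0, 0.0
    total = float(sum(charge_set.value(lb) for lb in labels))
    if covariance is not None:
        order = cov_labels if cov_labels is not None else labels
        idx = [order.index(lb) for lb in labels]
        block = np.asarray(covariance)[np.ix_(idx, idx)]
        var = float(np.ones(len(idx)) @ block @ np.ones(len(idx)))
        return total, float(np.sqrt(max(var, 0.0)))
    var = float(sum(charge_set.esu(lb) ** 2 for lb in labels))
    return total, float(np.sqrt(var))


@dataclass
class ChargeComparison:
    pearson: float
    n_pairs: int
    matched: list[str]
    unmatched_a: list[str] = field(default_factory=list)
    unmatched_b: list[str] = field(default_factory=list)
    include_hydrogens: bool = True


def pearson(set_a: ChargeSet, set_b: ChargeSet,
            include_hydrogens: bool = True,
            alias: dict[str, str] | None = None) -> ChargeComparison:
    """Pearson correlation between two charge sets over label-matched pairs.

    ``alias`` maps labels of ``set_a`` onto labels of ``set_b`` when the two
    sources name atoms differently.
    """
    alias = alias or {}
    a = set_a.subset(include_hydrogens)
    b = set_b.subset(include_hydrogens)
    b_labels = set(b.labels)
    pairs, matched = [], []
    for e in a.entries:
        target = alias.get(e.label, e.label)
        if target in b_labels:
            pairs.append((e.dq, b.value(target)))
            matched.append(e.label)
    if len(pairs) < 3:
        raise ValueError(f"need at least 3 matched pairs, got {len(pairs)}")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson coefficient undefined for zero variance")
    r = float(stats.pearsonr(x, y).statistic)
    return ChargeComparison(
        pearson=r, n_pairs=len(pairs), matched=matched,
        unmatched_a=[lb for lb in a.labels if lb not in matched],
        unmatched_b=[lb for lb in b.labels
                     if lb not in {alias.get(m, m) for m in matched}],
        include_hydrogens=include_hydrogens,
    )


def average_h_augmentation(set_without_h: ChargeSet, n_h: int) -> ChargeSet:
    """Append n_h hydrogen entries that each carry minus the mean non-H
    charge per proton, under the stated assumption of overall neutrality.
    Used as a control: it mimics knowing only that protons counterbalance
    the heavy-atom charges, without individual proton charges."""
    if n_h <= 0:
        raise ValueError("n_h must be positive")
    non_h_total = sum(e.dq for e in set_without_h.entries
                      if e.element.capitalize() != "H")
    per_h = -non_h_total / n_h
    entries = [ChargeEntry(**e.__dict__) for e in set_without_h.entries]
    for i in range(n_h):
        entries.append(ChargeEntry(label=f"Havg{i + 1}", element="H", dZ=1,
                                   nu=per_h, dq=per_h, esu=0.0))
    return ChargeSet(entries,
                     provenance=set_without_h.provenance + "+avgH")


def read_reference_charges(text: str, provenance: str = "reference") -> ChargeSet:
    """Two-column labelled table: 'label  charge' per line, '#' comments."""
    entries = []
    for line in text.splitlines():
        line = line.split("#")[0].strip()
        if not line:
            continue
        parts = line.split()
        label, q = parts[0], float(parts[1])
        element = "".join(c for c in label if c.isalpha())[:2].capitalize()
        if element and element[0] == "H":
            element = "H"
        entries.append(ChargeEntry(label=label, element=element, dq=q, nu=q))
    return ChargeSet(entries, provenance=provenance)
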