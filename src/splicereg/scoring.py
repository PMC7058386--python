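"""Score pipeline output against a synthetic truth manifest.

Sensitivity is the fraction of planted effects recovered in the pairwise
comparisons where they are expected (a dKO-specific gene must reach
significance in dKO vs ctrl, a sKO-specific one in sKO vs ctrl, and so
on); the empirical false discovery rate is the fraction of called items
not planted for that comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

from .synthetic import COMPARISONS, TruthManifest


@dataclass
class RecoveryScore:
    n_expected: int
    n_recovered: int
    n_called: int
    n_false: int

    @property
    def sensitivity(self) -> float:
        return self.n_recovered / self.n_expected if self.n_expected else float("nan")

    @property
    def fdr(self) -> float:
        return self.n_false / self.n_called if self.n_called else 0.0


def _comp_name(comparison: tuple[str, str]) -> str:
    return f"{comparison[0]}_vs_{comparison[1]}"


def score_de(manifest: TruthManifest, de_results: dict) -> RecoveryScore:
    """Score differential-gene calls; ``de_results`` maps comparison names
    ("dKO_vs_ctrl", ...) to DiffExprResult objects."""
    n_exp = n_rec = n_called = n_false = 0
    for comp in COMPARISONS:
        name = _comp_name(comp)
        if name not in de_results:
            continue
        expected = manifest.expected_de(comp)
        result = de_results[name]
        called = {g: "up" for g in result.up["gene_id"]}
        called.update({g: "down" for g in result.down["gene_id"]})
        n_exp += len(expected)
        n_rec += sum(called.get(g) == d for g, d in expected.items())
        n_called += len(called)
        n_false += sum(g not in expected for g in called)
    return RecoveryScore(n_exp, n_rec, n_called, n_false)


def score_as(manifest: TruthManifest, as_events: dict) -> RecoveryScore:
    """Score filtered splicing events; ``as_events`` maps comparison names
    to lists of kept (filtered + deduplicated) SpliceEvent objects."""
    n_exp = n_rec = n_called = n_false = 0
    for comp in COMPARISONS:
        name = _comp_name(comp)
        if name not in as_events:
            continue
        expected = manifest.expected_as(comp)
        called = {ev.event_id for ev in as_events[name]}
        n_exp += len(expected)
        n_rec += len(expected & called)
        n_called += len(called)
        n_false += len(called - expected)
    return RecoveryScore(n_exp, n_rec, n_called, n_false)


def score_binding(manifest: TruthManifest, calls: dict) -> float:
    """Fraction of planted bound/unbound designations recovered;
    ``calls`` maps event_id -> bool (bound)."""
    total = correct = 0
    for eid in manifest.bound_events:
        if eid in calls:
            total += 1
            correct += bool(calls[eid])
    for eid in manifest.unbound_events:
        if eid in calls:
            total += 1
            correct += not calls[eid]
    return correct / total if total else float("nan")
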