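"""Synthetic paired single-cell BCR repertoire generator.

Two generation modes per genotype preset:

* **empirical** — light-chain locus, gene usage, lambda-family weights and
  per-locus unproductive fractions are drawn from preset frequency tables,
  so downstream annotation + statistics can be checked as a clean parameter
  -recovery experiment (binomial/multinomial at known n).
* **mechanistic** — a per-cell state machine embodying the three factors
  that shape lambda light-chain output: (i) the probability that the Igl
  locus is open for rearrangement, (ii) the life-span of the developing
  cell (a per-attempt death hazard), and (iii) the efficiency of receptor
  editing (secondary Igk rearrangements walking to downstream J genes, then
  RS deletion and the Igl locus). Only orderings and limiting behaviours of
  this mode are asserted, never printed frequencies.

Junctional diversity follows the usual V(D)J model: geometric exonuclease
trimming per coding end (capped so the junction anchors survive) and
Poisson-distributed N additions. Productivity of each read is forced to a
Bernoulli draw from the preset's per-locus unproductive fraction by
adjusting junction-length parity (out-of-frame reads) or injecting /
scrubbing in-frame stop codons, so the classifier sees exact known rates.

``kappa_fraction`` is defined as the kappa share among cells with a
*productive* light chain (the quantity measured on real repertoires); the
raw locus draw is reweighted by per-locus productive rates so that the
productive-conditional share equals the preset value in expectation.

Randomness: one master seed; each cell uses a sub-stream derived from
(seed, cell index), so changing n_cells never reshuffles earlier cells.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .germline import (
    GermlineSet,
    Locus,
    SegmentClass,
    STOP_CODONS,
    build_default_germline,
)

LAMBDA_FAMILIES = ("lambda1", "lambda2", "lambda3")

#: cassette-consistent (V choices, J) per lambda family
_FAMILY_VJ: dict[str, tuple[tuple[str, ...], str]] = {
    "lambda1": (("Iglv1",), "Iglj1"),
    "lambda2": (("Iglv2", "Iglv3"), "Iglj2"),
    "lambda3": (("Iglv1",), "Iglj3"),
}


class PresetError(ValueError):
    """Contradictory or invalid genotype preset."""


@dataclass(frozen=True)
class JunctionParams:
    """Junctional-diversity model parameters (per coding end / junction)."""

    p_trim: float = 0.25          # geometric trimming parameter
    max_trim: int = 6             # nt cap per end; anchors always survive
    n_insert_heavy: float = 4.0   # Poisson mean, each of N1/N2 on Igh
    n_insert_light: float = 1.0   # Poisson mean on light chains


@dataclass(frozen=True)
class ClonalExpansion:
    """Inject clones that share one heavy-chain rearrangement."""

    n_clones: int = 1
    clone_mass: float = 0.05      # fraction of cells per clone
    forced_v_gene: str | None = None


@dataclass
class GenotypePreset:
    """Everything that distinguishes one simulated genotype from another."""

    name: str = "custom"
    mode: str = "empirical"  # or "mechanistic"

    # --- empirical tables -------------------------------------------------
    kappa_fraction: float = 0.83
    lambda_family_weights: dict[str, float] = field(
        default_factory=lambda: {"lambda1": 0.44, "lambda2": 0.41, "lambda3": 0.15}
    )
    igl_v2_share_of_lambda2: float = 0.5  # Iglv2 vs Iglv3 split inside lambda2
    igk_j_weights: dict[str, float] = field(
        default_factory=lambda: {
            "Igkj1": 0.40, "Igkj2": 0.30, "Igkj4": 0.20, "Igkj5": 0.10,
        }
    )
    unproductive_fraction: dict[str, float] = field(
        default_factory=lambda: {"IGH": 0.92, "IGK": 0.15, "IGL": 0.10}
    )
    unproductive_stop_fraction: float = 0.5  # stop_codon vs out_of_frame split

    # --- mechanistic parameters ------------------------------------------
    p_igk_productive: float = 0.5
    p_autoreactive_kappa: float = 0.05
    max_edit_attempts: int = 5
    p_igl_open: float = 0.3
    survival_halflife: float = 8.0  # attempts until P(alive) = 0.5
    kappa_silenced: bool = False
    kappa_forced_autoreactive: bool = False

    clonal_expansion: ClonalExpansion | None = None
    junction: JunctionParams = field(default_factory=JunctionParams)
    decoy_rate: float = 0.02

    def validate(self) -> None:
        if self.mode not in ("empirical", "mechanistic"):
            raise PresetError(f"unknown mode {self.mode!r}")
        probs = {
            "kappa_fraction": self.kappa_fraction,
            "p_igk_productive": self.p_igk_productive,
            "p_autoreactive_kappa": self.p_autoreactive_kappa,
            "p_igl_open": self.p_igl_open,
            "decoy_rate": self.decoy_rate,
            "igl_v2_share_of_lambda2": self.igl_v2_share_of_lambda2,
            "unproductive_stop_fraction": self.unproductive_stop_fraction,
            **{f"unproductive[{k}]": v for k, v in self.unproductive_fraction.items()},
        }
        for k, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise PresetError(f"{k} = {v} outside [0, 1]")
        for label, table in (
            ("lambda_family_weights", self.lambda_family_weights),
            ("igk_j_weights", self.igk_j_weights),
        ):
            if abs(sum(table.values()) - 1.0) > 1e-9:
                raise PresetError(f"{label} does not sum to 1")
            if any(v < 0 for v in table.values()):
                raise PresetError(f"{label} has negative weight")
        if set(self.lambda_family_weights) != set(LAMBDA_FAMILIES):
            raise PresetError("lambda_family_weights must cover lambda1/2/3")
        if self.mode == "empirical" and self.kappa_silenced and self.kappa_fraction > 0:
            raise PresetError(
                "kappa_fraction > 0 contradicts kappa_silenced=True"
            )

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GenotypePreset":
        d = dict(d)
        if d.get("clonal_expansion") is not None:
            d["clonal_expansion"] = ClonalExpansion(**d["clonal_expansion"])
        if "junction" in d and isinstance(d["junction"], dict):
            d["junction"] = JunctionParams(**d["junction"])
        p = cls(**d)
        p.validate()
        return p

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "GenotypePreset":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _scaled_igk_weights(jk5: float) -> dict[str, float]:
    base = {"Igkj1": 0.40, "Igkj2": 0.30, "Igkj4": 0.20}
    rest = 1.0 - jk5
    return {**{k: v * rest / 0.90 for k, v in base.items()}, "Igkj5": jk5}


def builtin_presets() -> dict[str, GenotypePreset]:
    """The shipped genotype presets.

    ``ctrl``/``bko`` encode the control and Kidins220 B-cell-knockout
    repertoire frequencies; ``wt_lambda`` is a lambda-only wild-type preset
    carrying the canonical mature lambda-family distribution (62/31/7);
    ``kappa_ko`` (silenced Igk locus) and ``macroself`` (every kappa chain
    autoreactive) are mechanistic.
    """
    ctrl = GenotypePreset(
        name="ctrl",
        mode="empirical",
        kappa_fraction=0.83,
        # Iglj1 44%, Iglv1 59% => lambda3 = 15%, lambda2 = 41%
        lambda_family_weights={"lambda1": 0.44, "lambda2": 0.41, "lambda3": 0.15},
        igk_j_weights=_scaled_igk_weights(0.10),
        unproductive_fraction={"IGH": 0.92, "IGK": 0.15, "IGL": 0.10},
    )
    bko = GenotypePreset(
        name="bko",
        mode="empirical",
        kappa_fraction=0.98,
        # Iglj1 69%, Iglv1 88% => lambda3 = 19%, lambda2 = 12%
        lambda_family_weights={"lambda1": 0.69, "lambda2": 0.12, "lambda3": 0.19},
        igk_j_weights=_scaled_igk_weights(0.142),
        unproductive_fraction={"IGH": 0.93, "IGK": 0.18, "IGL": 0.20},
        unproductive_stop_fraction=0.7,
        clonal_expansion=ClonalExpansion(1, 0.05, "Ighv10-1"),
    )
    wt_lambda = GenotypePreset(
        name="wt_lambda",
        mode="empirical",
        kappa_fraction=0.0,
        lambda_family_weights={"lambda1": 0.62, "lambda2": 0.31, "lambda3": 0.07},
        unproductive_fraction={"IGH": 0.92, "IGK": 0.15, "IGL": 0.10},
    )
    kappa_ko = GenotypePreset(
        name="kappa_ko",
        mode="mechanistic",
        kappa_fraction=0.0,
        kappa_silenced=True,
        p_igl_open=0.6,
        survival_halflife=8.0,
    )
    macroself = GenotypePreset(
        name="macroself",
        mode="mechanistic",
        kappa_forced_autoreactive=True,
        p_igl_open=0.3,
        survival_halflife=8.0,
    )
    return {p.name: p for p in (ctrl, bko, wt_lambda, kappa_ko, macroself)}


def get_preset(name: str) -> GenotypePreset:
    presets = builtin_presets()
    try:
        return presets[name]
    except KeyError:
        raise PresetError(
            f"unknown preset {name!r}; built-ins: {sorted(presets)}"
        ) from None


# ---------------------------------------------------------------------------
# rearrangement construction
# ---------------------------------------------------------------------------

FAILURE_NONE = "none"
FAILURE_OOF = "out_of_frame"
FAILURE_STOP = "stop_codon"
FAILURE_NON_IG = "non_ig"


@dataclass
class RearrangementTruth:
    """Ground truth for one simulated rearrangement."""

    locus: str
    v_name: str
    d_name: str | None
    j_name: str
    junction_nt: str
    sequence_nt: str
    is_productive_truth: bool
    failure_mode_truth: str = FAILURE_NONE
    n_edit_rounds: int = 0


@dataclass
class CellRecord:
    """One simulated B cell: paired heavy/light truth plus labels."""

    cell_id: str
    heavy: RearrangementTruth
    light: RearrangementTruth
    genotype: str
    clone_id: str | None = None


def _geom_trim(rng: np.random.Generator, p: float, cap: int) -> int:
    if cap <= 0 or p <= 0:
        return 0
    return int(min(rng.geometric(p) - 1, cap))


def _random_nt(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _scrub_stops(seq: list[str], start: int, end: int) -> None:
    """Destroy in-frame stop codons in seq[start:end) (frame from 0).

    Setting the middle base to C turns every stop (TAA/TAG/TGA) into a
    serine codon, mimicking a junctional nucleotide without moving anchors.
    """
    first = start + (-start) % 3
    for pos in range(first, end - 2, 3):
        codon = "".join(seq[pos : pos + 3])
        if codon in STOP_CODONS:
            seq[pos + 1] = "C"


def _find_stop(seq: str, end: int) -> bool:
    for pos in range(0, min(end, len(seq)) - 2, 3):
        if seq[pos : pos + 3] in STOP_CODONS:
            return True
    return False


def _build_rearrangement(
    gs: GermlineSet,
    locus: Locus,
    v_name: str,
    j_name: str,
    rng: np.random.Generator,
    jp: JunctionParams,
    productive: bool,
    failure_mode: str = FAILURE_NONE,
    d_name: str | None = None,
) -> RearrangementTruth:
    """Assemble one rearranged read with forced productivity outcome."""
    v = gs[v_name]
    j = gs[j_name]
    v_cap = min(jp.max_trim, len(v.sequence) - v.anchor_offset - 3)
    j_cap = min(jp.max_trim, j.anchor_offset)
    v_trim = _geom_trim(rng, jp.p_trim, v_cap)
    j_trim = _geom_trim(rng, jp.p_trim, j_cap)

    lam = jp.n_insert_heavy if locus is Locus.IGH else jp.n_insert_light
    insert = _random_nt(rng, int(rng.poisson(lam)))
    if d_name is not None:
        d = gs[d_name].sequence
        d_l = _geom_trim(rng, jp.p_trim, max(len(d) - 5, 0))
        d_r = _geom_trim(rng, jp.p_trim, max(len(d) - 5 - d_l, 0))
        core = d[d_l : len(d) - d_r]
        insert = insert + core + _random_nt(rng, int(rng.poisson(lam)))

    v_part = v.sequence[: len(v.sequence) - v_trim]
    j_part = j.sequence[j_trim:]
    j_anchor_rel = j.anchor_offset - j_trim

    def junction_len(ins: str) -> int:
        return (len(v_part) - v.anchor_offset) + len(ins) + j_anchor_rel + 3

    want_in_frame = productive or failure_mode == FAILURE_STOP
    rem = junction_len(insert) % 3
    if want_in_frame and rem:
        insert += _random_nt(rng, 3 - rem)
    elif not want_in_frame and failure_mode == FAILURE_OOF and rem == 0:
        insert += _random_nt(rng, 1 + int(rng.integers(0, 2)))

    if failure_mode == FAILURE_STOP:
        # place TAA on a codon boundary fully inside the insert
        p0 = len(v_part)
        q = p0 + (-p0) % 3
        while q + 3 > p0 + len(insert):
            insert += _random_nt(rng, 3)  # keeps frame
        off = q - p0
        insert = insert[:off] + "TAA" + insert[off + 3 :]

    seq = list(v_part + insert + j_part)
    junc_end = len(v_part) + len(insert) + j_anchor_rel + 3
    if productive:
        # scrub any stop codon from V start through the J anchor codon
        _scrub_stops(seq, 0, junc_end)
    sequence = "".join(seq)
    junction = sequence[v.anchor_offset : junc_end]
    return RearrangementTruth(
        locus=locus.value,
        v_name=v_name,
        d_name=d_name,
        j_name=j_name,
        junction_nt=junction,
        sequence_nt=sequence,
        is_productive_truth=productive,
        failure_mode_truth=FAILURE_NONE if productive else failure_mode,
    )


def _draw_failure(rng: np.random.Generator, preset: GenotypePreset) -> str:
    if rng.random() < preset.unproductive_stop_fraction:
        return FAILURE_STOP
    return FAILURE_OOF


def _draw_productive(
    rng: np.random.Generator, preset: GenotypePreset, locus: Locus
) -> tuple[bool, str]:
    u = preset.unproductive_fraction.get(locus.value, 0.0)
    if rng.random() < u:
        return False, _draw_failure(rng, preset)
    return True, FAILURE_NONE


#: geometric decay of intrinsic recombination propensity across ordered
#: heavy V/J genes; real gene usage is strongly non-uniform and stable
#: across genotypes, which is what makes cross-genotype usage correlations
#: informative.
HEAVY_USAGE_DECAY = 0.75


def _propensity_weights(n: int, decay: float = HEAVY_USAGE_DECAY) -> np.ndarray:
    w = decay ** np.arange(n)
    return w / w.sum()


def recombine_heavy(
    gs: GermlineSet,
    preset: GenotypePreset,
    rng: np.random.Generator,
    forced_v_gene: str | None = None,
    force_productive: bool = False,
) -> RearrangementTruth:
    """Draw one Igh VDJ rearrangement (fixed skewed gene propensities)."""
    vs = gs.by_class(Locus.IGH, SegmentClass.V)
    ds = gs.by_class(Locus.IGH, SegmentClass.D)
    js = gs.by_class(Locus.IGH, SegmentClass.J)
    v = forced_v_gene or vs[rng.choice(len(vs), p=_propensity_weights(len(vs)))].name
    d = ds[rng.integers(0, len(ds))].name if ds else None
    j = js[rng.choice(len(js), p=_propensity_weights(len(js)))].name
    if force_productive:
        ok, fm = True, FAILURE_NONE
    else:
        ok, fm = _draw_productive(rng, preset, Locus.IGH)
    return _build_rearrangement(
        gs, Locus.IGH, v, j, rng, preset.junction, ok, fm, d_name=d
    )


def _productive_conditional_locus(
    rng: np.random.Generator, preset: GenotypePreset
) -> Locus:
    """Draw the light locus so that P(IGK | productive) = kappa_fraction."""
    pk = 1.0 - preset.unproductive_fraction.get("IGK", 0.0)
    pl = 1.0 - preset.unproductive_fraction.get("IGL", 0.0)
    kf = preset.kappa_fraction
    if kf >= 1.0:
        return Locus.IGK
    if kf <= 0.0:
        return Locus.IGL
    if pk <= 0 or pl <= 0:
        raise PresetError("kappa_fraction unattainable with productive rate 0")
    wk = kf / pk
    wl = (1.0 - kf) / pl
    return Locus.IGK if rng.random() < wk / (wk + wl) else Locus.IGL


def rearrange_light_empirical(
    gs: GermlineSet, preset: GenotypePreset, rng: np.random.Generator
) -> RearrangementTruth:
    """Draw one light-chain rearrangement from preset frequency tables."""
    if preset.mode != "empirical":
        raise PresetError("rearrange_light_empirical requires empirical mode")
    if preset.kappa_silenced and preset.kappa_fraction > 0:
        raise PresetError("kappa_fraction > 0 contradicts kappa_silenced=True")
    locus = _productive_conditional_locus(rng, preset)
    if locus is Locus.IGK:
        vs = gs.by_class(Locus.IGK, SegmentClass.V)
        v = vs[rng.integers(0, len(vs))].name
        names = sorted(preset.igk_j_weights)
        w = np.array([preset.igk_j_weights[n] for n in names])
        j = names[rng.choice(len(names), p=w / w.sum())]
    else:
        fams = LAMBDA_FAMILIES
        w = np.array([preset.lambda_family_weights[f] for f in fams])
        fam = fams[rng.choice(len(fams), p=w / w.sum())]
        v_choices, j = _FAMILY_VJ[fam]
        if len(v_choices) == 1:
            v = v_choices[0]
        else:  # lambda2: Iglv2 vs Iglv3
            v = (
                "Iglv2"
                if rng.random() < preset.igl_v2_share_of_lambda2
                else "Iglv3"
            )
    ok, fm = _draw_productive(rng, preset, locus)
    return _build_rearrangement(gs, locus, v, j, rng, preset.junction, ok, fm)


def rearrange_light_mechanistic(
    gs: GermlineSet, preset: GenotypePreset, rng: np.random.Generator
) -> RearrangementTruth | None:
    """Sequential kappa-then-lambda rearrangement with receptor editing.

    Returns ``None`` when the cell dies before producing a non-autoreactive
    productive light chain. Surviving cells always carry a productive chain.
    Secondary Igk rearrangements walk to higher-numbered functional J genes
    across two alleles; exhaustion (or ``max_edit_attempts``) models RS
    deletion, after which only the Igl locus (if open) remains.
    """
    if preset.mode != "mechanistic":
        raise PresetError("rearrange_light_mechanistic requires mechanistic mode")
    hazard = 1.0 - 0.5 ** (1.0 / max(preset.survival_halflife, 1e-9))
    igk_js = [
        s.name for s in gs.by_class(Locus.IGK, SegmentClass.J, functional_only=True)
    ]
    kappa_sequence = igk_js + igk_js  # two alleles, ascending J per allele
    igl_open = rng.random() < preset.p_igl_open

    k_idx = 0
    edits = 0
    attempt = 0
    max_attempts = 10_000
    while attempt < max_attempts:
        attempt += 1
        if rng.random() < hazard:
            return None  # cell death
        kappa_available = (
            not preset.kappa_silenced
            and k_idx < len(kappa_sequence)
            and edits <= preset.max_edit_attempts
        )
        if kappa_available:
            j = kappa_sequence[k_idx]
            k_idx += 1
            if rng.random() < preset.p_igk_productive:
                autoreactive = preset.kappa_forced_autoreactive or (
                    rng.random() < preset.p_autoreactive_kappa
                )
                if not autoreactive:
                    vs = gs.by_class(Locus.IGK, SegmentClass.V)
                    v = vs[rng.integers(0, len(vs))].name
                    r = _build_rearrangement(
                        gs, Locus.IGK, v, j, rng, preset.junction, True
                    )
                    r.n_edit_rounds = edits
                    return r
                edits += 1  # editing continues past an autoreactive chain
            else:
                edits += 1
        elif igl_open:
            fams = LAMBDA_FAMILIES
            w = np.array([preset.lambda_family_weights[f] for f in fams])
            fam = fams[rng.choice(len(fams), p=w / w.sum())]
            v_choices, j = _FAMILY_VJ[fam]
            v = (
                v_choices[0]
                if len(v_choices) == 1
                else v_choices[int(rng.integers(0, len(v_choices)))]
            )
            if rng.random() < preset.p_igk_productive:
                r = _build_rearrangement(
                    gs, Locus.IGL, v, j, rng, preset.junction, True
                )
                r.n_edit_rounds = edits
                return r
        # else: kappa exhausted and Igl closed -- wait for the clock
    return None


# ---------------------------------------------------------------------------
# repertoire-level simulation and serialization
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = [
    "sequence_id",
    "cell_id",
    "chain",
    "locus",
    "v_call_truth",
    "d_call_truth",
    "j_call_truth",
    "junction_truth",
    "productive_truth",
    "failure_mode_truth",
    "n_edit_rounds",
    "clone_id",
    "genotype",
]


def _cell_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(index)]))


def simulate_cells(
    gs: GermlineSet,
    preset: GenotypePreset,
    n_cells: int,
    seed: int,
) -> list[CellRecord]:
    """Simulate ``n_cells`` paired B cells (mechanistic mode: survivors)."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    preset.validate()

    # clone membership decided up-front from a dedicated sub-stream
    clone_of: dict[int, int] = {}
    clone_heavy: dict[int, RearrangementTruth] = {}
    ce = preset.clonal_expansion
    if ce is not None and ce.n_clones > 0 and ce.clone_mass > 0:
        crng = _cell_rng(seed, 2**31 + 1)
        for c in range(ce.n_clones):
            clone_heavy[c] = recombine_heavy(
                gs, preset, crng, forced_v_gene=ce.forced_v_gene,
                force_productive=True,
            )
        u = crng.random(n_cells)
        for i in range(n_cells):
            slot = int(u[i] // ce.clone_mass)
            if u[i] < ce.clone_mass * ce.n_clones:
                clone_of[i] = slot

    cells: list[CellRecord] = []
    index = 0
    attempts = 0
    while len(cells) < n_cells:
        attempts += 1
        if attempts > 1000 * n_cells + 1000:
            raise RuntimeError(
                "mechanistic simulation: survival too low to reach n_cells"
            )
        rng = _cell_rng(seed, index)
        i = index
        index += 1
        if preset.mode == "empirical":
            light = rearrange_light_empirical(gs, preset, rng)
        else:
            light = rearrange_light_mechanistic(gs, preset, rng)
            if light is None:
                continue
        if i in clone_of:
            heavy = clone_heavy[clone_of[i]]
            clone_id = f"clone{clone_of[i]:02d}"
        else:
            heavy = recombine_heavy(gs, preset, rng)
            clone_id = None
        cells.append(
            CellRecord(
                cell_id=f"cell{len(cells):06d}",
                heavy=heavy,
                light=light,
                genotype=preset.name,
                clone_id=clone_id,
            )
        )
    return cells


def simulate_repertoire(
    gs: GermlineSet,
    preset: GenotypePreset,
    n_cells: int,
    seed: int,
    fasta_path: str | Path | None = None,
    manifest_path: str | Path | None = None,
) -> tuple[list[CellRecord], list[tuple[str, str]], pd.DataFrame]:
    """Simulate a repertoire; optionally write reads FASTA + truth manifest.

    Returns ``(cells, reads, manifest)`` where ``reads`` is a list of
    ``(header, sequence)`` with headers ``cellNNNNNN|heavy`` /
    ``cellNNNNNN|light`` / ``decoyNNNNNN|decoy``. Decoy reads are random
    DNA injected at ``preset.decoy_rate`` per Ig read to exercise the
    non-Ig classifier. Deterministic for fixed seed.
    """
    cells = simulate_cells(gs, preset, n_cells, seed)
    reads: list[tuple[str, str]] = []
    rows: list[dict] = []
    for cell in cells:
        for chain, r in (("heavy", cell.heavy), ("light", cell.light)):
            sid = f"{cell.cell_id}|{chain}"
            reads.append((sid, r.sequence_nt))
            rows.append(
                {
                    "sequence_id": sid,
                    "cell_id": cell.cell_id,
                    "chain": chain,
                    "locus": r.locus,
                    "v_call_truth": r.v_name,
                    "d_call_truth": r.d_name or "",
                    "j_call_truth": r.j_name,
                    "junction_truth": r.junction_nt,
                    "productive_truth": r.is_productive_truth,
                    "failure_mode_truth": r.failure_mode_truth,
                    "n_edit_rounds": r.n_edit_rounds,
                    "clone_id": cell.clone_id or "",
                    "genotype": cell.genotype,
                }
            )
    drng = _cell_rng(seed, 2**31 + 2)
    n_decoys = int(drng.binomial(len(reads), preset.decoy_rate))
    for k in range(n_decoys):
        sid = f"decoy{k:06d}|decoy"
        seq = _random_nt(drng, 200)
        reads.append((sid, seq))
        rows.append(
            {
                "sequence_id": sid,
                "cell_id": f"decoy{k:06d}",
                "chain": "decoy",
                "locus": "",
                "v_call_truth": "",
                "d_call_truth": "",
                "j_call_truth": "",
                "junction_truth": "",
                "productive_truth": False,
                "failure_mode_truth": FAILURE_NON_IG,
                "n_edit_rounds": 0,
                "clone_id": "",
                "genotype": preset.name,
            }
        )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)

    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for sid, seq in reads:
                fh.write(f">{sid}\n{seq}\n")
    if manifest_path is not None:
        manifest.to_csv(manifest_path, sep="\t", index=False)
    return cells, reads, manifest
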