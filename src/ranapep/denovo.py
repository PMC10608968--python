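"""De novo sequence inference from spectra.

Automates the manual ladder-walking used to read frog-peptide spectra:

* a *spectrum graph* whose nodes are prefix-mass hypotheses derived
  from b- (or c-) series peaks, with virtual source (mass 0) and sink
  (the precursor's total residue mass), and whose edges are
  residue-mass gaps within tolerance;
* highest-scoring source-to-sink paths read off as sequence tags
  (Leu/Ile gaps are labelled 'J'; two-residue composite gaps are
  reported as paired-residue alternatives);
* in-silico verification of candidate sequences against a spectrum;
* greedy maximal-overlap assembly of full sequences from overlapping
  proteolytic fragments, the step that recovers intact peptides (e.g.
  bradykinin from its 1-7 and 5-9 pieces) when the parent ion itself is
  barely detectable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .chem import (AMIDE_DELTA, PROTON, RESIDUE_MASSES, WATER, CTerminus,
                   Peptide, peptide_mono_mass, ppm_error)
from .fragments import MODES, NH2, NH3, FragmentationMode, predict_ions
from .annotate import CoverageReport, DEFAULT_TOL_PPM, match_peaks, sequence_coverage

__all__ = ["SpectrumGraph", "SequenceTag", "AssemblyResult", "build_graph",
           "denovo_tags", "verify_candidate", "assemble_from_fragments"]

# canonical single-residue edge alphabet: one code per distinct mass
# (I/J fold into L -> labelled 'J' for the isobaric pair)
_EDGE_RESIDUES = {code: m for code, m in RESIDUE_MASSES.items()
                  if code not in ("I", "J")}
_PAIR_GAPS = sorted(
    {(round(_EDGE_RESIDUES[a] + _EDGE_RESIDUES[b], 6),
      tuple(sorted((a, b))))
     for a, b in itertools.product(_EDGE_RESIDUES, repeat=2)})


def _edge_label(code: str) -> str:
    return "J" if code == "L" else code


@dataclass
class SpectrumGraph:
    """DAG of prefix-mass hypotheses ordered by mass.

    Node attributes: ``mass`` (Da), ``peak_index`` (None for the
    virtual source/sink), ``intensity``.  Edge attribute ``labels`` is
    a tuple of residue codes (or ``(XY)`` composite alternatives)
    consistent with the mass gap.
    """

    graph: nx.DiGraph
    source: int
    sink: int
    tol_ppm: float
    spectrum: object = None
    series_hypothesis: str = "b"
    c_terminus: CTerminus = CTerminus.FREE_ACID

    @property
    def n_peak_nodes(self) -> int:
        return sum(1 for _, d in self.graph.nodes(data=True)
                   if d["peak_index"] is not None)


@dataclass(frozen=True)
class SequenceTag:
    """A de novo sequence hypothesis read from a spectrum-graph path."""

    residues: str
    start_mass: float
    end_mass: float
    peak_indices: tuple[int, ...]
    score: int
    summed_intensity: float
    charge_penalty: int = 0   # sum of (hypothesis charge - 1) over nodes
    complement_count: int = 0  # nodes whose complementary ion is present
    explained_peaks: int = 0   # spectrum peaks the candidate explains in silico
    absent_predictions: int = 0  # predicted ions with no matching peak
    verification_ppm: float = 0.0  # summed |ppm| over verification matches

    @property
    def is_full(self) -> bool:
        return self.start_mass == 0.0

    @property
    def composite_gaps(self) -> int:
        """Number of two-residue composite gaps left unresolved."""
        return self.residues.count("(")


def _gap_tolerance(tol_ppm: float, mass: float) -> float:
    return tol_ppm * 1e-6 * max(mass, 200.0)


def build_graph(s, series_hypothesis: str = "b",
                tol_ppm: float = DEFAULT_TOL_PPM,
                c_terminus: CTerminus = CTerminus.FREE_ACID,
                charge_hypotheses: tuple[int, ...] = (1, 2),
                composite_gaps: bool = True) -> SpectrumGraph:
    """Build the spectrum graph under a b- or c-series hypothesis.

    Each peak is interpreted as a singly/doubly protonated prefix
    fragment (minus a proton for b; minus an additional NH3 for c).
    Edges connect node pairs whose mass gap matches a residue mass
    within tolerance; Lys (128.09496) and Gln (128.05858) stay distinct
    edges at <= 10 ppm for fragment masses below ~1.8 kDa.  When no
    single residue fits, two-residue composite gaps are enumerated.

    Each peak node also records whether the spectrum contains the
    complementary C-terminal ion (the y peak for a b prefix, the z-dot
    peak for a c prefix): genuine ladder peaks usually have their
    complement, peaks misread under the wrong series/charge usually do
    not, and tag ranking uses this to break score ties.
    """
    if series_hypothesis not in ("b", "c"):
        raise ValueError("series_hypothesis must be 'b' or 'c'")
    if s.precursor_charge is None:
        raise ValueError("precursor charge unknown: cannot place the sink")
    offset = 0.0 if series_hypothesis == "b" else NH3
    total = s.precursor_neutral_mass - WATER
    if c_terminus is CTerminus.AMIDE:
        total -= AMIDE_DELTA
    cterm_mass = WATER + (AMIDE_DELTA if c_terminus is CTerminus.AMIDE else 0.0)
    # complementary suffix ion for a prefix of mass m: y for b, z-dot for c
    comp_offset = cterm_mass - (0.0 if series_hypothesis == "b" else NH2)
    peak_mzs = s.mz_array

    def has_complement(prefix_mass: float) -> bool:
        target = (total - prefix_mass) + comp_offset + PROTON
        tol = tol_ppm * 1e-6 * max(target, 200.0)
        i = int(np.searchsorted(peak_mzs, target))
        for k in (i - 1, i):
            if 0 <= k < len(peak_mzs) and abs(peak_mzs[k] - target) <= tol:
                return True
        return False

    g = nx.DiGraph()
    g.add_node(0, mass=0.0, peak_index=None, intensity=0.0, charge=1)
    node_id = 1
    for idx, pk in enumerate(s.peaks):
        for z in charge_hypotheses:
            prefix = (pk.mz - PROTON) * z - offset
            if prefix <= 0 or prefix >= total - 0.5 * _gap_tolerance(tol_ppm, total):
                continue
            g.add_node(node_id, mass=prefix, peak_index=idx,
                       intensity=pk.intensity, charge=z,
                       complement=has_complement(prefix))
            node_id += 1
    sink = node_id
    g.add_node(sink, mass=total, peak_index=None, intensity=0.0, charge=1)

    nodes = sorted(g.nodes, key=lambda n: g.nodes[n]["mass"])
    masses = {n: g.nodes[n]["mass"] for n in nodes}
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            gap = masses[v] - masses[u]
            if gap < 50.0:
                continue
            if gap > 2 * 186.08 + 1:
                break
            tol = _gap_tolerance(tol_ppm, max(masses[v], masses[u]))
            labels = [_edge_label(code)
                      for code, m in _EDGE_RESIDUES.items()
                      if abs(gap - m) <= tol]
            if not labels and composite_gaps and gap > 100.0:
                pairs = {pair for m, pair in _PAIR_GAPS if abs(gap - m) <= tol}
                if pairs:
                    alts = sorted("".join(_edge_label(c) for c in p)
                                  for p in pairs)
                    labels = ["(" + "|".join(alts) + ")"]
            if labels:
                g.add_edge(u, v, labels=tuple(sorted(labels)))
    return SpectrumGraph(g, source=0, sink=sink, tol_ppm=tol_ppm,
                         spectrum=s, series_hypothesis=series_hypothesis,
                         c_terminus=c_terminus)


def _tag_sequences(residues: str) -> list[str]:
    """Expand a tag into concrete sequences: 'J' becomes Leu-mass 'J',
    composite '(AB|BA)' gaps branch into their alternatives."""
    parts: list[list[str]] = [[""]]
    i = 0
    while i < len(residues):
        if residues[i] == "(":
            close = residues.index(")", i)
            alts = residues[i + 1:close].split("|")
            parts.append(alts)
            i = close + 1
        else:
            parts.append([residues[i]])
            i += 1
    seqs = [""]
    for options in parts:
        seqs = [s + o for s in seqs for o in options]
        if len(seqs) > 16:   # cap combinatorial blow-up
            seqs = seqs[:16]
    return seqs


def _verification_score(sg: SpectrumGraph,
                        tag: SequenceTag) -> tuple[int, int, float]:
    """Verification rescore for a complete candidate.

    Returns (explained spectrum peaks, predicted ions with no peak,
    summed |ppm| over the matches) for the candidate's full in-silico
    fragment prediction.  On clean data the true sequence explains
    every ladder peak at near-zero mass error and predicts nothing
    absent; a rearrangement consistent with the same total mass either
    predicts ions the spectrum lacks or rides on coincidental matches
    that sit several ppm off."""
    s = sg.spectrum
    if s is None or not tag.is_full:
        return (0, 0, 0.0)
    mode = MODES["HCD"] if sg.series_hypothesis == "b" else MODES["EThcD"]
    best: tuple[int, int, float] | None = None
    for seq in _tag_sequences(tag.residues):
        try:
            p = Peptide(seq, sg.c_terminus)
        except ValueError:
            continue
        ions = [i for i in predict_ions(p, mode) if i.visible]
        anns = match_peaks(s, ions, sg.tol_ppm)
        explained = len({a.peak_index for a in anns})
        absent = len(ions) - len(anns)
        total_ppm = sum(abs(a.ppm_deviation) for a in anns)
        cand = (explained, absent, total_ppm)
        if best is None or (explained, -absent, -total_ppm) > \
                (best[0], -best[1], -best[2]):
            best = cand
    return best or (0, 0, 0.0)


def denovo_tags(sg: SpectrumGraph, max_tags: int = 5,
                max_paths: int = 50000, rescore: bool = True) -> list[SequenceTag]:
    """Highest-scoring source-to-sink tags, deduplicated and sorted.

    Path score is the number of supporting peak nodes; ties break by
    fewer unresolved composite gaps, then complementary-ion support,
    then parsimony of charge hypotheses, then summed supporting
    intensity, then lexicographic label.  Complete candidates are then
    re-ranked by in-silico verification — the count of spectrum peaks
    the candidate's full predicted fragment complement explains — the
    same confirmation step applied to manually read sequences.  If no
    full path exists the best partial tags (paths ending short of the
    sink) are returned instead.
    """
    g, source, sink = sg.graph, sg.source, sg.sink
    results: list[SequenceTag] = []
    budget = [max_paths]

    def emit(path: list[int], labels: list[str]) -> None:
        peak_nodes = [n for n in path if g.nodes[n]["peak_index"] is not None]
        results.append(SequenceTag(
            residues="".join(labels),
            start_mass=g.nodes[path[0]]["mass"],
            end_mass=g.nodes[path[-1]]["mass"],
            peak_indices=tuple(g.nodes[n]["peak_index"] for n in peak_nodes),
            score=len(peak_nodes),
            summed_intensity=sum(g.nodes[n]["intensity"] for n in peak_nodes),
            charge_penalty=sum(g.nodes[n].get("charge", 1) - 1
                               for n in peak_nodes),
            complement_count=sum(bool(g.nodes[n].get("complement"))
                                 for n in peak_nodes)))

    def dfs(node: int, path: list[int], labels: list[str],
            require_sink: bool) -> None:
        if budget[0] <= 0:
            return
        if node == sink:
            budget[0] -= 1
            emit(path, labels)
            return
        succs = sorted(g.successors(node), key=lambda n: g.nodes[n]["mass"])
        if not succs and not require_sink and len(path) > 1:
            budget[0] -= 1
            emit(path, labels)
            return
        for nxt in succs:
            for lab in g.edges[node, nxt]["labels"]:
                dfs(nxt, path + [nxt], labels + [lab], require_sink)

    dfs(source, [source], [], require_sink=True)
    if not results:  # no complete path: fall back to partial tags
        dfs(source, [source], [], require_sink=False)
    # dedupe by residue string, keep the best-scoring instance
    best: dict[str, SequenceTag] = {}
    for tag in results:
        prev = best.get(tag.residues)
        if prev is None or (tag.score, tag.summed_intensity) > \
                (prev.score, prev.summed_intensity):
            best[tag.residues] = tag
    path_key = lambda t: (-t.score, t.composite_gaps, -t.complement_count,
                          t.charge_penalty, -t.summed_intensity, t.residues)
    ordered = sorted(best.values(), key=path_key)
    if rescore and sg.spectrum is not None:
        shortlist = ordered[:max(10 * max_tags, 100)]
        from dataclasses import replace as _replace
        rescored = []
        for t in shortlist:
            explained, absent, vppm = _verification_score(sg, t)
            rescored.append(_replace(t, explained_peaks=explained,
                                     absent_predictions=absent,
                                     verification_ppm=vppm))
        ordered = sorted(rescored,
                         key=lambda t: (-t.explained_peaks,
                                        t.absent_predictions,
                                        t.verification_ppm) + path_key(t))
    return ordered[:max_tags]


def verify_candidate(p: Peptide, s, tol_ppm: float = DEFAULT_TOL_PPM,
                     mode: FragmentationMode | None = None) -> CoverageReport:
    """Check a candidate sequence against a spectrum in silico.

    Predicts the full fragment complement for the spectrum's activation
    mode, matches it, and reports cleavage coverage together with the
    precursor mass agreement.  A precursor disagreeing with the
    candidate mass beyond tolerance is reported as a mismatch (in Da),
    but matching is still performed.
    """
    if mode is None:
        mode = MODES.get(s.mode or "HCD", MODES["HCD"])
    ions = predict_ions(p, mode)
    annotations = match_peaks(s, ions, tol_ppm)
    report = sequence_coverage(p, annotations, spectrum_id=s.title)
    theor = peptide_mono_mass(p)
    precursor_ppm = mismatch = None
    neutral = s.precursor_neutral_mass
    if neutral is not None:
        precursor_ppm = ppm_error(neutral, theor)
        if precursor_ppm > tol_ppm:
            mismatch = neutral - theor
    return CoverageReport(
        spectrum_id=report.spectrum_id, length=report.length,
        site_evidence=report.site_evidence,
        matched_ion_count=report.matched_ion_count,
        precursor_ppm=precursor_ppm, precursor_mismatch_da=mismatch)


@dataclass(frozen=True)
class AssemblyResult:
    """An assembled sequence and the layout of its source fragments."""

    sequence: str
    layout: tuple[tuple[str, int], ...]   # (fragment, 0-based offset)
    min_overlap_used: int

    def __post_init__(self) -> None:
        for frag, off in self.layout:
            if self.sequence[off:off + len(frag)] != frag:
                raise ValueError(f"fragment {frag} not at offset {off}")


def _suffix_prefix_overlap(a: str, b: str) -> int:
    for k in range(min(len(a), len(b)) - 1, 0, -1):
        if a.endswith(b[:k]):
            return k
    return 0


def assemble_from_fragments(fragments: list[str],
                            min_overlap: int = 3) -> list[AssemblyResult]:
    """Greedy maximal-overlap assembly of exact suffix-prefix matches.

    Fragments contained in another fragment are absorbed into it;
    remaining pieces are merged largest-overlap-first while an overlap
    of at least ``min_overlap`` exists.  Unmergeable fragments come
    back as singletons.  Output order is deterministic and, for inputs
    whose pairwise maximal overlaps are unique, independent of the
    input order.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    items = [{"seq": f, "layout": [(f, 0)]} for f in sorted(set(fragments))]

    def absorb_containments() -> None:
        changed = True
        while changed:
            changed = False
            for a, b in itertools.permutations(items, 2):
                if a["seq"] != b["seq"] and a["seq"] in b["seq"]:
                    off = b["seq"].index(a["seq"])
                    b["layout"].extend((f, o + off) for f, o in a["layout"])
                    items.remove(a)
                    changed = True
                    break

    absorb_containments()
    merges: list[int] = []
    while len(items) > 1:
        best = None
        for a, b in itertools.permutations(items, 2):
            k = _suffix_prefix_overlap(a["seq"], b["seq"])
            if k >= min_overlap:
                key = (k, a["seq"], b["seq"])
                if best is None or key > best[0]:
                    best = (key, a, b)
        if best is None:
            break
        (k, _, _), a, b = best
        off = len(a["seq"]) - k
        a["seq"] = a["seq"] + b["seq"][k:]
        a["layout"].extend((f, o + off) for f, o in b["layout"])
        items.remove(b)
        merges.append(k)
        absorb_containments()
    out = []
    for it in sorted(items, key=lambda d: d["seq"]):
        out.append(AssemblyResult(
            sequence=it["seq"],
            layout=tuple(sorted(it["layout"], key=lambda t: (t[1], t[0]))),
            min_overlap_used=min(merges) if merges else 0))
    return out
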