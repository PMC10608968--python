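# ranapep

Top-down de novo MS/MS sequencing toolkit for frog skin defense
peptides, built around the peptidome of the Central Slovenian agile
frog *Rana dalmatina*: 28 secreted peptides spanning the brevinin 1/2,
temporin, melittin-related (MRP) and bradykinin-related (BRP) families.

Ranid frogs secrete short cationic membrane-active peptides whose
sequences must usually be read directly from intact-peptide tandem
mass spectra, because no genome is available. `ranapep` implements the
full computational side of that workflow:

* **Mass arithmetic** — monoisotopic peptide masses with C-terminal
  amidation (−0.98402 Da) and intramolecular disulfide bonds
  (−2.01565 Da per S–S), charge-state and isotopologue m/z, ppm errors.
* **Fragment prediction** — b/y (CID/HCD) and c/z• (ETD/EThcD) series;
  secondary Lys/Lys-Lys losses from y ions; w ions from side-chain
  radical losses of z• ions (isopropyl −43.05478 Da marks Leu, ethyl
  −29.03913 Da marks Ile); visibility rules for cleavages inside an
  intact disulfide loop (the "Rana box") and their re-exposure when
  ETD opens the S–S bond.
* **Synthetic spectra + MGF I/O** — a seeded simulator with peak
  dropout, ppm jitter and noise peaks (raw study spectra are
  request-only), and Mascot-generic-format reading/writing via
  pyteomics.
* **Annotation** — nearest-peak ppm matching, cleavage-site coverage,
  and w-ion-based Leu/Ile calling that abstains on conflicting or
  missing evidence.
* **De novo sequencing** — spectrum-graph tag generation with
  composite two-residue gaps, verification rescoring against the full
  predicted fragment complement, and greedy maximal-overlap assembly
  of full sequences from proteolytic pieces.
* **Pipeline** — rule-based family classification, targeted
  bradykinin-variant search, and a recomputed mass/ppm/family report
  over the bundled 28-peptide inventory.

## Worked example

```python
from ranapep import (Peptide, CTerminus, peptide_mono_mass, isotopologue_mz,
                     simulate_spectrum, SimulationConfig, HCD, ETHCD,
                     build_graph, denovo_tags, leu_ile_discriminate,
                     assemble_from_fragments)

# brevinin 1Db: 24-mer with the C-terminal CSITKKC disulfide loop
b1db = Peptide("FFPAFLKVAAKVVPSILCSITKKC", disulfides=((18, 24),))
print(round(peptide_mono_mass(b1db), 3))          # 2607.468
print(round(isotopologue_mz(peptide_mono_mass(b1db), 5, 1), 3))  # 522.702

# read a peptide back from its own simulated HCD spectrum
p = Peptide("FLPLIAGLLGKLF", CTerminus.AMIDE)     # temporin 1Da
sp = simulate_spectrum(p, HCD, SimulationConfig(seed=1))
g = build_graph(sp, "b", tol_ppm=10, c_terminus=CTerminus.AMIDE)
print(denovo_tags(g, 1)[0].residues)              # FJPJJAGJJGKJF

# resolve the J (Leu-or-Ile) positions from EThcD w ions
sp2 = simulate_spectrum(p, ETHCD, SimulationConfig(seed=1))
cand = Peptide("FJPJJAGJJGKJF", CTerminus.AMIDE)
for call in leu_ile_discriminate(cand, sp2, tol_ppm=10):
    print(call.position, call.call.value)          # 2 Leu, 4 Leu, 5 Ile, ...

# rebuild bradykinin from its proteolytic pieces
print(assemble_from_fragments(["RPPGFSP", "FSPFR"], 3)[0].sequence)
# RPPGFSPFR
```

The de novo tag keeps `J` wherever Leu and Ile are indistinguishable
by mass alone; the EThcD step then assigns Leu at positions 2, 4, 8,
9, 12 and Ile at position 5.

A command-line interface mirrors the library
(`ranapep simulate|annotate|denovo|assemble|report|targeted`), and the
numbered drivers under `analysis/` rerun the study-level analyses,
writing their tables to `results/`.

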