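# kcxlink

Toolkit for **cysteine-enabled cleavable cross-linking mass spectrometry
(XL-MS)** with heterobifunctional lysine-cysteine (K-C) cross-linkers.

Commercial NHS ester-haloacetamide reagents (SIA, SIAB, SBAP) bridge a lysine
side-chain amine to a cysteine thiol, but the resulting thioether is not
MS-cleavable, which makes proteome-wide identification of the cross-linked
peptide pairs hard. Oxidizing the cross-linked cysteine to a sulfoxide
introduces a labile C-S bond: collisional activation then splits the
cross-link into two single-peptide signature fragments that can be sequenced
independently. `kcxlink` implements the full computational side of this
workflow for proteomics groups analyzing such data:

* **chemistry** — elemental-composition/monoisotopic-mass model for peptides,
  linkers, oxidized cross-links and their cleavage products. For an oxidized
  cross-link of two peptides α (lysine side) and β (cysteine side):

  ```
  M(precursor) = M(α) + M(β) + M(bridge) + M(O) − 2·M(H)
  α_S = α + sulfenic-acid remnant          (linker-dependent)
  α_T = α_S − H2O                          (dehydrated thiol remnant)
  β_A = β − H2S = β − 33.987721 Da         (alkene remnant, linker-independent)
  M(α_S) + M(β_A) = M(precursor)           (exact mass conservation)
  ```

  plus the diagnostic 107.004 Da RSOH neutral loss of oxidized
  carbamidomethyl cysteine.
* **spectra** — centroided MS run I/O (MGF and mzML) with MS1→MS2→MS3 scan
  lineage.
* **identify** — in-silico tryptic digestion with reversal decoys, MS2
  signature-pair detection, MS3 peptide matching, MS1/MS2/MS3 integration
  (MSn mode) or single-spectrum stepped-HCD MS2 search, target-decoy FDR
  ((TD−DD)/TT at the cross-link spectrum match level) and aggregation into
  unique residue-to-residue linkages.
* **structmap** — mapping linkages onto experimental/predicted structures:
  minimal Cα–Cα distances with homo-oligomer rescue, strict <30 Å
  satisfaction, AlphaFold PAE/pLDDT confidence gating, secondary-structure
  preference profiles.
* **network** — protein–protein interaction network assembly from
  inter-protein linkages, overlap with reference edge sets, complex-subunit
  recovery, multi-linker concordance.
* **synthetic** — ground-truthed generators (proteomes, planted cross-links,
  MSn/stepped-HCD runs, toy structures) so the entire pipeline is testable
  offline.

## Worked example

The two synthetic peptides Ac-SAKAYEHR (α, K3) and Ac-LADVCAHER (β, C5)
cross-linked by SIA:

```sh
$ kcxlink calc --linker SIA --alpha "Ac-SAKAYEHR:K3" --beta "Ac-LADVCAHER:C5" --charge 4
linker             SIA (spacer 4.2 A)
intact_ox_addition 55.9898 Da
precursor          529.2485 (4+)
alpha_S            547.2402 (2+)
alpha_T            538.2349 (2+)
beta_A             511.2567 (2+)
rsoh_loss          107.0041 Da
```

The precursor is the oxidized cross-linked pair at 4+; `alpha_S`/`beta_A`
are the two signature fragments produced by C-S cleavage (both at 2+ here),
and `alpha_T` is the dehydrated form of `alpha_S`. These theoretical values
agree with published observed values for this pair within a few ppm. The
same numbers drive identification: a candidate MS2 peak pair is accepted as
a signature pair only when the two fragment neutrals sum to the precursor
neutral, and each MS3 spectrum is matched against peptides carrying the
corresponding remnant mass.

A full synthetic round trip:

```sh
kcxlink simulate --seed 5 --n-proteins 20 --n-crosslinks 10 --out sim/
kcxlink search --fasta sim/proteome.fasta --run sim/run.mgf --out search/
kcxlink net --links search/linkages.tsv --out net/
```

`search/csms.tsv` lists one scored α-β assignment per precursor scan with
its decoy class and FDR status; `search/linkages.tsv` the unique K-C
residue pairs. On a noiseless simulation every planted link is recovered as
the rank-1 match and survives 1% FDR.

## Documentation

`docs/methods.md` describes the mass model, the search and FDR procedure,
the synthetic-data generator and its limitations, and the numerical
conventions (tolerances, tie-breaking, thresholds) in detail.
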