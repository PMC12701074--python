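"""Shared fixtures: the worked-example peptide pair, synthetic runs, and a
minimal mzML writer for lineage round-trip tests."""

from __future__ import annotations

import base64

import numpy as np
import pytest

from kcxlink.chemistry import CrossLinkedPair, ModifiedPeptide, get_linker


@pytest.fixture(scope="session")
def sr8() -> ModifiedPeptide:
    """Ac-SAKAYEHR, the synthetic lysine-containing peptide (link site K3)."""
    return ModifiedPeptide("SAKAYEHR", nterm="acetyl")


@pytest.fixture(scope="session")
def lr9() -> ModifiedPeptide:
    """Ac-LADVCAHER, the synthetic cysteine-containing peptide (link site C5)."""
    return ModifiedPeptide("LADVCAHER", nterm="acetyl")


@pytest.fixture(scope="session")
def sia_pair(sr8, lr9) -> CrossLinkedPair:
    return CrossLinkedPair(sr8, 3, lr9, 5, get_linker("SIA"))


def _b64(arr) -> str:
    return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode()


def _spectrum_xml(index, scan, level, mz, inten, prec=None) -> str:
    prec_xml = ""
    if prec:
        ref = f' spectrumRef="scan={prec["parent"]}"' if prec.get("parent") else ""
        prec_xml = f"""
      <precursorList count="1"><precursor{ref}>
        <selectedIonList count="1"><selectedIon>
          <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{prec['mz']}"/>
          <cvParam cvRef="MS" accession="MS:1000041" name="charge state" value="{prec['z']}"/>
        </selectedIon></selectedIonList>
        <activation><cvParam cvRef="MS" accession="MS:1000422" name="beam-type collision-induced dissociation" value=""/></activation>
      </precursor></precursorList>"""
    return f"""
    <spectrum index="{index}" id="controllerType=0 controllerNumber=1 scan={scan}" defaultArrayLength="{len(mz)}">
      <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{level}"/>{prec_xml}
      <binaryDataArrayList count="2">
        <binaryDataArray><cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
          <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
          <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
          <binary>{_b64(mz)}</binary></binaryDataArray>
        <binaryDataArray><cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
          <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
          <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
          <binary>{_b64(inten)}</binary></binaryDataArray>
      </binaryDataArrayList>
    </spectrum>"""


def write_minimal_mzml(path, spectra) -> None:
    """Write a minimal centroided mzML; ``spectra`` entries are dicts with
    scan, level, mz, intensity and an optional prec={'mz','z','parent'}."""
    body = "".join(
        _spectrum_xml(i, s["scan"], s["level"], s["mz"], s["intensity"], s.get("prec"))
        for i, s in enumerate(spectra)
    )
    doc = f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <run id="r">
    <spectrumList count="{len(spectra)}">{body}
    </spectrumList>
  </run>
</mzML>"""
    with open(path, "w") as fh:
        fh.write(doc)
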