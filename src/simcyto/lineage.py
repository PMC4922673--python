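"""Reference data for the *Simulium cholodkovskii* lineage.

This module encodes the published chromosomal survey of the lineage as
machine-readable inputs: the three species (two Palearctic, collected in
sympatry on the Tuul River at sites 1 and 2; one Nearctic at site 3), the
per-population sample sizes (138 larvae: 72 females, 66 males), the
frequency of rearranged constituents for all 58 recorded rearrangements,
the sex-chromosome censuses, and the diagnostic inversion sets used in the
sympatric hybrid screen.

Only one polymorphism's genotype counts were published in full (IS-22 at
site 1: ss = 29, si = 34, ii = 7); for the remaining cells the survey
reports rounded frequencies and footnote censuses.  ``build_records``
therefore reconstructs a deterministic per-larva genotype table whose
realised counts reproduce every published cell exactly under the survey's
rounding dialect, with the jointly constrained carriers (the absolutely
linked IS-20/IS-21 pair, the nested Y-linked IS series, the X/Y double
heterozygotes, and the single partial-hybrid male) placed explicitly.
"""

from __future__ import annotations

from .popgen import LarvaRecord
from .phylogeny import (ABSENT, POLYMORPHIC, FIXED, X_LINKED, Y_LINKED,
                        CharacterMatrix)

SPECIES = ("cholodkovskii", "decimatum", "nigricoxum")
OUTGROUPS = ("erythrocephalum", "vittatum")

#: (species, site, n_females, n_males)
POPULATIONS = (
    ("cholodkovskii", 1, 38, 32),
    ("cholodkovskii", 2, 12, 8),
    ("decimatum", 1, 7, 13),
    ("decimatum", 2, 3, 3),
    ("nigricoxum", 3, 12, 10),
)

#: rearrangements fixed across the whole lineage (frequency 1.00 everywhere)
LINEAGE_FIXED = (
    "T(I;III)", "IS-17", "IS-18", "IS-19", "IL-1", "IL-17",
    "IIS-1", "IIS-5", "IIS-6a", "IIL-1", "IIL-2", "IIIS-1",
    "IIIL-2", "IIIL-15", "IIIL-23",
)

#: all surveyed rearrangements, in map order
ALL_NAMES = (
    "T(I;III)",
    "IS-17", "IS-18", "IS-19", "IS-20", "IS-21", "IS-22", "IS-23", "IS-24",
    "IS-25", "IS-26", "IS-27", "IS-28",
    "IL-1", "IL-17", "IL-18", "IL-19", "IL-20", "IL-21", "IL-22", "IL-23",
    "IL-24", "IL-25", "IL-26", "IL-27", "IL-28",
    "IIS-1", "IIS-4", "IIS-5", "IIS-6a", "IIS-7", "IIS-8", "IIS-9", "IIS-10",
    "IIS-11", "IIS 43Hb",
    "IIL-1", "IIL-2", "IIL-16", "IIL-17", "IIL-18", "IIL 69Hb",
    "IIIS-1", "IIIS-3",
    "IIIL-2", "IIIL-15", "IIIL-16", "IIIL-17", "IIIL-18", "IIIL-19",
    "IIIL-20", "IIIL-21", "IIIL-22", "IIIL-23", "IIIL-25", "IIIL-24",
    "IIIL 85d", "IIIL repattern",
)

#: published frequency-survey cells, one string per population column
#: (chol site 1, chol site 2, dec site 1, dec site 2, nig site 3);
#: sex-linked entries are categorical: X = X-linked, Y = Y-linked,
#: Y/X = Y-linked with a rare X occurrence
PUBLISHED_CELLS = {
    "T(I;III)": ("1.00", "1.00", "1.00", "1.00", "1.00"),
    "IS-17": ("1.00", "1.00", "1.00", "1.00", "1.00"),
    "IS-18": ("1.00", "1.00", "1.00", "1.00", "1.00"),
    "IS-19": ("1.00", "1.00", "1.00", "1.00", "1.00"),
    "IS-20": ("0.97", "0.95", "0.02", "", ""),
    "IS-21": ("0.97", "0.95", "0.02", "", ""),
    "IS-22": ("0.34", "0.22", "", "", ""),
    "IS-23": ("", "", "Y/X", "Y/X", ""),
    "IS-24": ("", "", "Y", "Y", ""),
    "IS-25": ("", "", "Y", "", ""),
    "IS-26": ("", "", "", "Y", ""),
    "IS-27": ("", "0.02", "", "", ""),
    "IS-28": ("0.01", "", "", "", ""),
    "IL-1": ("1.00", "1.00", "1.00", "1.00", "1.00"),
    "IL-17": ("1.00", "1.00", "1.00", "1.00", "1.00"),
    "IL-18": ("", "", "", "", "1.00"),
    "IL-19": ("", "", "", "0.08", ""),
    "IL-20": ("<0.01", "", "0.02", "", ""),
    "IL-21": ("", "", "0.02", "", ""),
    "IL-22": ("<0.01", "", "", "", ""),
    "IL-23": ("0.01", "", "", "", ""),
    "IL-24": ("<0.01", "", "", "", ""),
    "IL-25": ("<0.01", "", "", "", ""),
    "IL-26": ("<0.01", "", "", "", ""),
    "IL-27": ("0.03", "", "", "", ""),
    "IL-28": ("<0.01", "", "", "", ""),
    "IIS-1": ("1.00", "1.00", "1.00", "1.00", "1.00"),
    "IIS-4": ("1.00", "1.00", "1.00", "1.00", "X"),
    "IIS-5": ("1.00", "1.00", "1.00", "1.00", "1.00"),
    "IIS-6a": ("1.00", "1.00", "1.00", "1.00", "1.00"),
    "IIS-7": ("", "", "0.88", "0.83", ""),
    "IIS-8": ("0.02", "", "", "", ""),
    "IIS-9": ("<0.01", "", "", "", ""),
    "IIS-10": ("", "", "", "", "Y"),
    "IIS-11": ("0.01", "0.02", "", "", ""),
    "IIS 43Hb": ("<0.01", "", "", "", ""),
    "IIL-1": ("1.00", "1.00", "1.00", "1.00", "1.00"),
    "IIL-2": ("1.00", "1.00", "1.00", "1.00", "1.00"),
    "IIL-16": ("0.74", "0.70", "0.05", "0.08", ""),
    "IIL-17": ("0.23", "0.25", "0.02", "", ""),
    "IIL-18": ("0.03", "0.05", "0.92", "0.92", ""),
    "IIL 69Hb": ("", "", "0.02", "", ""),
    "IIIS-1": ("1.00", "1.00", "1.00", "1.00", "1.00"),
    "IIIS-3": ("<0.01", "", "", "", ""),
    "IIIL-2": ("1.00", "1.00", "1.00", "1.00", "1.00"),
    "IIIL-15": ("1.00", "1.00", "1.00", "1.00", "1.00"),
    "IIIL-16": ("0.96", "1.00", "", "", ""),
    "IIIL-17": ("", "", "0.02", "", ""),
    "IIIL-18": ("<0.01", "", "", "", ""),
    "IIIL-19": ("", "", "", "0.17", ""),
    "IIIL-20": ("0.01", "0.02", "", "", ""),
    "IIIL-21": ("<0.01", "0.02", "", "", ""),
    "IIIL-22": ("<0.01", "", "0.02", "", ""),
    "IIIL-23": ("1.00", "1.00", "1.00", "1.00", "1.00"),
    "IIIL-25": ("0.07", "", "0.05", "", ""),
    "IIIL-24": ("<0.01", "", "", "", ""),
    "IIIL 85d": ("", "", "0.02", "", ""),
    "IIIL repattern": ("0.01", "", "", "", ""),
}

#: diagnostic inversions for the sympatric hybrid screen, with the published
#: minimum parental frequencies they satisfy
DIAGNOSTICS_CHOLODKOVSKII = {"IS-20": 0.95, "IS-21": 0.95, "IIIL-16": 0.95}
DIAGNOSTICS_DECIMATUM = {"IIS-7": 0.82, "IIL-18": 0.82}


# ---------------------------------------------------------------------------
# deterministic per-larva reconstruction


def _build_population(species, site, n_f, n_m, columns, configs,
                      flags=None) -> list[LarvaRecord]:
    """columns: name -> "fixed" | {"si": [...], "ii": [...] | "rest of those
    with data"}; configs: index -> sex configuration (others default)."""
    n = n_f + n_m
    genomes = [{name: 0 for name in ALL_NAMES} for _ in range(n)]
    for name, spec in columns.items():
        if spec == "fixed":
            for g in genomes:
                g[name] = 2
            continue
        si = spec.get("si", ())
        ii = spec.get("ii", ())
        if ii == "rest":
            ii = [i for i in range(n) if i not in set(si) | set(spec.get("ss", ()))]
        for i in si:
            genomes[i][name] = 1
        for i in ii:
            genomes[i][name] = 2
    records = []
    for i in range(n):
        sex = "female" if i < n_f else "male"
        cfg = (configs or {}).get(i, "X0X0" if sex == "female" else "X0Y0")
        rec_flags = frozenset((flags or {}).get(i, ()))
        records.append(LarvaRecord(
            larva_id=f"{species}-s{site}-{i + 1:03d}", site=site,
            species=species, sex=sex, genotypes=genomes[i],
            sex_config=cfg, flags=rec_flags))
    return records


def _cholodkovskii_site1() -> list[LarvaRecord]:
    cols = {name: "fixed" for name in LINEAGE_FIXED}
    cols["IIS-4"] = "fixed"
    cols.update({
        # absolutely linked pair: identical carriers, heterozygous males kept
        # clear of the IIL-18 carriers so the sympatric screen stays clean
        "IS-20": {"si": range(66, 70), "ii": "rest"},
        "IS-21": {"si": range(66, 70), "ii": "rest"},
        "IS-22": {"ii": range(0, 7), "si": range(7, 41)},   # ss=29, si=34, ii=7
        "IIIL-16": {"si": range(0, 6), "ii": "rest"},
        # IIL homologue classes: 39 x 16/16, 23 x 16/17, 3 x 16/18,
        # 1 x 17/18, 4 x 17/17  (104:32:4 of 140 homologues)
        "IIL-16": {"ii": range(0, 39), "si": range(39, 65)},
        "IIL-17": {"si": list(range(39, 62)) + [65], "ii": range(66, 70)},
        "IIL-18": {"si": range(62, 66)},
        "IS-28": {"si": [6, 7]},
        "IL-20": {"si": [8]},
        "IL-22": {"si": [9]},
        "IL-23": {"si": [10, 11]},
        "IL-24": {"si": [12]},
        "IL-25": {"si": [13]},
        "IL-26": {"si": [14]},
        "IL-27": {"si": [15, 16, 17, 18]},
        "IL-28": {"si": [19]},
        "IIS-8": {"si": [20, 21, 22]},
        "IIS-9": {"si": [23]},
        "IIS-11": {"si": [24, 25]},
        "IIS 43Hb": {"si": [26]},
        "IIIS-3": {"si": [27]},
        "IIIL-18": {"si": [28]},
        "IIIL-20": {"si": [29, 30]},
        "IIIL-21": {"si": [31]},
        "IIIL-22": {"si": [32]},
        "IIIL-24": {"si": [33]},
        "IIIL-25": {"si": range(34, 44)},
        "IIIL repattern": {"si": [37, 38]},   # one female, one male
    })
    flags = {37: {"unresolved_repattern"}, 38: {"unresolved_repattern"}}
    return _build_population("cholodkovskii", 1, 38, 32, cols, {}, flags)


def _cholodkovskii_site2() -> list[LarvaRecord]:
    cols = {name: "fixed" for name in LINEAGE_FIXED}
    cols["IIS-4"] = "fixed"
    cols["IIIL-16"] = "fixed"
    cols.update({
        "IS-20": {"si": [0, 1], "ii": "rest"},
        "IS-21": {"si": [0, 1], "ii": "rest"},
        "IS-22": {"ii": [2], "si": range(3, 10)},
        # IIL classes: 10 x 16/16, 7 x 16/17, 1 x 16/18, 1 x 17/18, 1 x 17/17
        "IIL-16": {"ii": range(0, 10), "si": range(10, 18)},
        "IIL-17": {"si": list(range(10, 17)) + [18], "ii": [19]},
        "IIL-18": {"si": [17, 18]},
        "IS-27": {"si": [2]},
        "IIS-11": {"si": [3]},
        "IIIL-20": {"si": [4]},
        "IIIL-21": {"si": [5]},
    })
    return _build_population("cholodkovskii", 2, 12, 8, cols, {})


def _decimatum_site1() -> list[LarvaRecord]:
    cols = {name: "fixed" for name in LINEAGE_FIXED}
    cols["IIS-4"] = "fixed"
    configs = {6: "X0X1",
               7: "X0Y0", 8: "X0Y0", 9: "X0Y0", 10: "X0Y0",
               11: "X0Y1", 12: "X0Y1", 13: "X0Y1", 14: "X0Y1",
               15: "X0Y2", 16: "X0Y2", 17: "X0Y2",
               18: "X0Y3",
               19: "unresolved"}   # IS-20,21 male; homologues unattributable
    cols.update({
        "IS-23": {"si": [6, 11, 12, 13, 14, 15, 16, 17, 18]},
        "IS-24": {"si": [15, 16, 17, 18]},
        "IS-25": {"si": [18]},
        "IS-20": {"si": [19]},
        "IS-21": {"si": [19]},
        "IIS-7": {"si": [19, 0, 1], "ss": [2], "ii": "rest"},
        # IIL classes: 17 x 18/18, 18/16 at larvae 19 and 5, 18/17 at larva 7
        "IIL-18": {"si": [19, 5, 7], "ii": "rest"},
        "IIL-16": {"si": [19, 5]},
        "IIL-17": {"si": [7]},
        "IL-20": {"si": [8]},
        "IL-21": {"si": [9]},
        "IIIL-17": {"si": [10]},
        "IIIL-22": {"si": [0]},
        "IIIL-25": {"si": [1, 2]},
        "IIL 69Hb": {"si": [3]},
        "IIIL 85d": {"si": [4]},
    })
    return _build_population("decimatum", 1, 7, 13, cols, configs)


def _decimatum_site2() -> list[LarvaRecord]:
    cols = {name: "fixed" for name in LINEAGE_FIXED}
    cols["IIS-4"] = "fixed"
    configs = {3: "X0Y1", 4: "X0Y2", 5: "X0Y4"}
    cols.update({
        "IS-23": {"si": [3, 4, 5]},
        "IS-24": {"si": [4, 5]},
        "IS-26": {"si": [5]},
        "IIS-7": {"si": [0, 1], "ii": "rest"},
        "IIL-18": {"si": [0], "ii": "rest"},
        "IIL-16": {"si": [0]},
        "IL-19": {"si": [1]},
        "IIIL-19": {"si": [2, 3]},
    })
    return _build_population("decimatum", 2, 3, 3, cols, configs)


def _nigricoxum_site3() -> list[LarvaRecord]:
    cols = {name: "fixed" for name in LINEAGE_FIXED}
    cols["IL-18"] = "fixed"
    n_f = 12
    cols.update({
        "IIS-4": {"ii": range(0, n_f), "si": range(n_f, 22)},   # X-linked
        "IIS-10": {"si": range(n_f, 22)},                       # Y-linked
    })
    configs = {i: ("X1X1" if i < n_f else "X1Y1") for i in range(22)}
    return _build_population("nigricoxum", 3, 12, 10, cols, configs)


def build_records() -> list[LarvaRecord]:
    """All 138 larva records of the survey (72 females, 66 males)."""
    return (_cholodkovskii_site1() + _cholodkovskii_site2()
            + _decimatum_site1() + _decimatum_site2()
            + _nigricoxum_site3())


def sympatric_records(records=None) -> list[LarvaRecord]:
    """The 116 Tuul River larvae screened for hybrids (sites 1 and 2)."""
    records = records if records is not None else build_records()
    return [r for r in records if r.species in ("cholodkovskii", "decimatum")]


# ---------------------------------------------------------------------------
# character matrix for the cytophylogeny

#: outgroup resolvability by arm: IL aligns only with S. erythrocephalum,
#: IIS is too scrambled to align with either outgroup
ARM_RESOLVABLE = {
    "IS": frozenset(OUTGROUPS),
    "IL": frozenset({"erythrocephalum"}),
    "IIS": frozenset(),
    "IIL": frozenset(OUTGROUPS),
    "IIIS": frozenset(OUTGROUPS),
    "IIIL": frozenset(OUTGROUPS),
    "": frozenset(OUTGROUPS),       # whole-arm interchange
}


def _arm_of(name: str) -> str:
    if name.startswith("T("):
        return ""
    return name.split("-")[0].split(" ")[0]


def character_matrix(table=None, linkage=None) -> CharacterMatrix:
    """Build the taxa x rearrangement state matrix from the frequency survey.

    ``table`` is a :class:`~simcyto.popgen.FrequencyTable` over the lineage
    records (built from :func:`build_records` when omitted).  Outgroups carry
    none of the lineage rearrangements; the unresolved IIIL repattern has no
    determinable polarity and is scored unresolvable."""
    from .popgen import frequency_table
    if table is None:
        table = frequency_table(build_records(), ALL_NAMES)
    states = {}
    for name in table.names:
        for sp in SPECIES:
            mark = None
            for g in table.groups:
                if g[0] == sp and (name, g) in table.marks:
                    mark = table.marks[(name, g)]
            if mark is not None:
                states[(sp, name)] = X_LINKED if mark == "X" else Y_LINKED
                continue
            if not table.present(name, sp):
                states[(sp, name)] = ABSENT
                continue
            pooled = table.species_frequency(name, sp)
            states[(sp, name)] = FIXED if pooled == 1 else POLYMORPHIC
        for og in OUTGROUPS:
            states[(og, name)] = ABSENT
    resolvable = {}
    for name in table.names:
        if name == "IIIL repattern":
            resolvable[name] = frozenset()
        else:
            resolvable[name] = ARM_RESOLVABLE[_arm_of(name)]
    return CharacterMatrix(
        ingroup=list(SPECIES), outgroups=list(OUTGROUPS),
        characters=list(table.names), states=states,
        resolvable_against=resolvable)
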