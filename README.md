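# spectrophores

One-dimensional descriptors computed from three-dimensional atomic property
fields, for ligand-based virtual screening, scaffold hopping and QSAR.

A **spectrophore** describes how a molecular conformation would bind a panel
of artificial receptors. Each receptor is a rectangular cage around the
molecule whose 12 edge midpoints carry values P(c, i) ∈ {+1, −1} (six of
each sign). For atoms *j* with property values A(j, p), the interaction with
cage *c* is

    V(c, p) = −100 · Σᵢ Σⱼ A(j, p) · P(c, i) / rᵢⱼ

with rᵢⱼ the cage-point/atom distance in Å. The molecule is rotated through
a dense Euler grid (the *accuracy*, default 20°), the cage rebuilt at every
orientation so the molecule-to-cage distance stays at the *resolution*
(default 3 Å), and the per-(cage, property) **maximum** kept. Four atomic
properties are used — EEM partial charges, rule-based lipophilicities,
shape deviations and EEM electrophilicities — giving 4 × 12 = 48 values
with the default non-stereospecific cage set (72 with the 18 stereospecific
cages, 120 with all 30). Because only maxima over orientations enter, the
descriptor is independent of input position and orientation, and Euclidean
distances between spectrophores measure 3D property-field similarity
irrespective of the underlying topology — the basis for scaffold hopping.

See `docs/methods.md` for the model details, parameter semantics, numerical
choices and limitations.

## Worked example

Compute spectrophores for a 3D SDF file (a lone water molecule here) with
the default settings:

```sh
$ spectrophores calc --in water.sdf --out water_spec.tsv
INFO spectrophores: settings: SpectrophoreSettings(accuracy=20, resolution=3.0,
     stereospecificity='none', normalization='none')
INFO spectrophores: wrote 1 spectrophores of 48 values to water_spec.tsv

$ cut -f1-7 water_spec.tsv
#settings	accuracy=20	resolution=3.0	stereospecificity=none	normalization=none
title	v001	v002	v003	v004	v005	v006
water	2.0139198558331017	2.4649328130475685	1.893814633206825	5.188739800001556	8.467206523461519	5.8092860693550445
```

Values 1–12 are the maximized charge-block interactions, one per cage (the
first cage reaches 2.014, the fifth 8.467 — water's dipole couples strongly
to that sign pattern); values 13–24 are the lipophilicity block, 25–36 the
shape block, 37–48 the electrophilicity block. The same result is available
in Python:

```python
from spectrophores import read_sdf, spectrophore, SpectrophoreSettings

mol = read_sdf("water.sdf")[0]
record = spectrophore(mol, settings=SpectrophoreSettings(accuracy=20))
record.values[:6]
# array([2.0139, 2.4649, 1.8938, 5.1887, 8.4672, 5.8093])
```

Similarity searching and conformer handling:

```sh
spectrophores distance --query query.tsv --db library.tsv --cutoff 50 --out hits.tsv
spectrophores merge --in conformers.tsv --out merged.tsv   # element-wise max by title
spectrophores fixture --kind chiral_tetrahedron --out probe.sdf
```

Spectrophores are only comparable at identical settings (in particular the
resolution); all distance operations refuse mixed settings.

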