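# Methods

## Model overview

The package implements lattice-field QSAR for a congeneric series: aligned
molecules are described by interaction-field values on a shared rectangular
grid, the field matrix is regressed on pIC50 by partial least squares, and
the model is judged by leave-one-out cross-validation, an external test set,
and Y-randomization. Assumptions inherited from the method family:

- the series shares a rigid common scaffold and a meaningful common
  alignment; activity differences come from substituent variation;
- activities are on the log scale (pIC50 = 6 − log10 IC50[μM]) and the
  structure–activity relationship is locally linear in field space;
- the test set interpolates the training set (its activity range must nest
  inside the training range; splits are re-drawn until that holds).

## Fields and their parameters

| parameter | default | units | rationale |
|---|---|---|---|
| grid spacing | 2.0 | Å | the conventional lattice pitch for these fields; halving it quadruples columns with little extra information |
| grid margin | 4.0 | Å | keeps every probe interaction inside the box (≈ 2–3 × vdW radius) |
| probe | sp³ C, r = 1.70 Å, ε = 0.107 kcal/mol, q = +1 e | | the standard single-probe convention |
| energy truncation | ±30 | kcal/mol | bounds the r⁻¹² singularity; steric values at the cap mark nodes inside the molecular volume |
| dielectric | ε(r) = r | | distance-dependent screening; with the Coulomb constant 332.0637 kcal·Å·mol⁻¹·e⁻² gives E = 332.0637·q_iq_p/r² |
| Gaussian attenuation α | 0.3 | Å⁻² | the literature default for similarity indices |
| similarity steric weight | r_vdw³ | Å³ | atomic-volume surrogate |
| column filter σ | 2.0 (energies), 0.02 (similarity) | field units | similarity indices are dimensionless and ~100× smaller than kcal/mol energies, so a single cutoff cannot serve both families; each default drops only near-constant columns of its own family |
| block scaling | equal total variance per field kind | | prevents the largest-magnitude field from dominating the covariance-driven PLS directions |

Electrostatic values at sterically clashed nodes carry no information and are
replaced by their column mean computed over the unclashed training compounds;
the same stored means are applied to test compounds.

All filter, scaling and substitution statistics are learned on the training
rows only and applied unchanged to test rows.

## Charges and atom typing

Partial charges, when not supplied by the input (MOL2 charges take
precedence), come from iterative partial equalization of orbital
electronegativities: per-element quadratic electronegativity functions
(sigma-framework sp³ parameters, no aromatic π correction), damping 0.5ᵏ,
six iterations, transfers applied synchronously so the result is independent
of atom order and conserves total charge exactly. Donor/acceptor typing is
deliberately simple — every N/O is an acceptor, an N/O with a covalently
bound hydrogen is also a donor — and hydrophobic weights are a per-element
lipophilicity lookup. These rules are coarse compared to full
pharmacophoric typing but are exact and auditable, which is what the
synthetic acceptance surface needs.

## PLS and model selection

NIPALS with a single response is deterministic: the first weight vector is
X'y, scores are deflated from X, and the cumulative coefficient vector is
B = W(P'W)⁻¹c. At full rank it coincides with ordinary least squares (tested
against a normal-equations oracle). Cross-validation is leave-one-out; PRESS
and q² = 1 − PRESS/TSS are accumulated per component count, TSS about the
mean of the full cross-validated set. The ONC is the smallest component
count whose q² reaches 95% of the profile maximum — a parsimony rule chosen
because component-selection conventions vary; with a non-positive best q²
the argmax is returned. SEE and F use n − c − 1 degrees of freedom, which
reproduces published F values from published (n, c, r²) triples within
rounding. Field contributions are Σ|coef|·sd per kind on the scaled block,
normalised to one.

## External validation and Y-randomization

The through-origin battery is computed exactly as the standard formulas
read, with one numerical guard: R² − R0² is clamped at zero before the
square root in rm², because a through-origin fit can numerically exceed the
centered fit. Threshold verdicts use strict inequalities. The overall
verdict requires condition 1, (3a or 3b), (4a or 4b), 5 and 6.
Y-randomization permutes the response without replacement from a seeded
generator and reruns the identical recipe including ONC re-selection.

## Contour volumes

StDev×Coeff maps multiply each kept column's standard deviation by its
regression coefficient. Because scaling multiplies sd and divides the
coefficient by the same factor, the product is scale-convention invariant
and lives in activity units. The "80%/20% contribution" levels are
interpreted as cumulative-|value|-mass quantiles: the favored isosurface
encloses the positive nodes carrying the top 20% of positive mass, and the
disfavored isosurface the top 20% of negative mass (symmetric rule; the
convention name is written into the OpenDX header). Volumes are exported as
OpenDX scalar fields; the in-memory linearization is x-fastest while the DX
data stream is z-fastest per the format, and the writer re-orders
accordingly.

## Synthetic congeneric series

The generator emulates the structure of a real analogue series without
claiming chemistry: a fixed 10-atom bicyclic scaffold (shared coordinates,
hence pre-aligned) with two substituent sites growing chains of 1–4 atoms
at 0.9 Å steps with ±0.45 Å positional jitter; substituent elements from
{C, N, O, F}, partial charges U(−0.5, 0.5) e, hydrophobic weights U(0, 1),
donor/acceptor flags Bernoulli(0.3). Defaults mirror a typical study: 40
compounds, 75/25 split under the nesting condition, activity noise 0.3
pIC50 units around a base of 6.8.

Activities are planted linearly in true similarity-field values at three
effect nodes near the substituent sites — steric +0.25, hydrophobic −1.5,
donor +1.2 (mixed signs on purpose; similarity values are negative). These
sizes give a planted signal of ≈ 0.8–1.0 pIC50 sd against 0.3 noise, i.e. a
strong but not noiseless relationship. A single seed drives three fixed-
offset sub-streams (geometry, noise, split) so stages rerun stably.

Recovery runs model with the steric + hydrophobic + donor + acceptor
similarity kinds — the field combination a practitioner would select here
(and the combination the reference study's chosen model used): the
electrostatic field is uninformative by construction in the planted model,
and including it hands a fifth of the descriptor variance to pure noise.
Acceptor is retained as an uninformative control kind.

What passing recovery does and does not show: the generator has no
conformational flexibility, no correlated substituent chemistry, no
alignment error and Gaussian noise only, so success demonstrates the
correctness of the pipeline's computation and bookkeeping — not that the
method will achieve similar statistics on laboratory data.

## Numerical choices and degenerate inputs

- distances to grid nodes are floored at 1e-10 Å before any power law;
- NIPALS stops early when the residual weight or score norm falls below
  1e-12 (fewer components than requested are returned);
- constant response vectors, zero-variance columns everywhere, empty blocks
  after filtering, non-positive IC50s and sub-3-atom superpositions are
  rejected with explicit errors;
- Kabsch superposition rejects collinear skeletons (second singular value
  test) and always returns a proper rotation (determinant correction);
- perfect fits report SEE = 0 and F = +inf.

## Problem sizes

The bundled synthetic studies use 40 compounds on grids of roughly
10×10×9 nodes (spacing 2 Å), a few hundred kept columns, LOO over 30
training compounds and up to 10 components; a full pipeline run takes well
under a second, and the entire test suite a few seconds.

## Known limitations

- No conformer generation, force-field minimisation, flexible alignment or
  protonation handling: structures are taken as given.
- Charge and typing schemes are element-level approximations; parity with
  any commercial implementation's numerics is not claimed, and the exact
  grid/probe settings used by published studies are generally unreported.
- The published headline statistics of the reference compound series cannot
  be recomputed because its 3-D structures were never deposited; only the
  printed-number-derivable quantities are reproduced, the rest of the
  evidence being property-based.
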