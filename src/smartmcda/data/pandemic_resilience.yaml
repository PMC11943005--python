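# Packaged decision model: three resilience strategies for the Romanian
# healthcare system evaluated over four criterion dimensions by SMART.
# Weights follow the dimension-definition table (HR 0.20, service planning
# 0.30, budget 0.35, legal 0.15); the alternate label order used by the
# published performance matrix (budget listed first at 0.35) is carried as
# alt_label metadata — both keyings give identical scores because the numeric
# pipeline is driven by the attribute-to-weight assignment, which is
# consistent everywhere.
name: pandemic-resilience
rank_total: 14
dimensions:
  - id: K1
    label: Human resource management
    alt_label: Budget allocation  # published matrix swaps K1/K3 labels
    weight: 0.20
  - id: K2
    label: Healthcare service planning
    weight: 0.30
  - id: K3
    label: Budget allocation
    alt_label: Human resource management
    weight: 0.35
  - id: K4
    label: Legal framework
    weight: 0.15
attributes:
  - id: A1
    dimension: K1
    label: Shortage of trained and qualified personnel
  - id: A2.1
    dimension: K2
    label: Proper planning and organization of medical services
  - id: A2.2
    dimension: K2
    label: Educational and informational campaigns for the population
  - id: A2.3
    dimension: K2
    label: Access to medical services for all patients, including vulnerable groups
  - id: A2.4
    dimension: K2
    label: Cost-effective alternative solutions such as telemedicine
  - id: A3
    dimension: K3
    label: Health-system underfunding
  - id: A4
    dimension: K4
    label: Lack of harmonized legislation
alternatives:
  - id: S1
    label: Prioritization in emergency regime
    strategy_weight: 0.35
    importance_rank: 1
  - id: S2
    label: Medium-term solutions
    strategy_weight: 0.35
    importance_rank: 2
  - id: S3
    label: Long-term prioritization
    strategy_weight: 0.35
    importance_rank: 3
ranks:
  S1: {A1: 1, A2.1: 3, A2.2: 1, A2.3: 3, A2.4: 2, A3: 1, A4: 3}
  S2: {A1: 2, A2.1: 2, A2.2: 2, A2.3: 1, A2.4: 3, A3: 2, A4: 2}
  S3: {A1: 3, A2.1: 1, A2.2: 3, A2.3: 2, A2.4: 1, A3: 3, A4: 1}
metadata:
  # published per-alternative coefficient column; the S3 value (1.50)
  # conflicts with rank x strategy_weight (1.05) and never enters U_j.
  alternative_coefficients: {S1: 0.35, S2: 0.70, S3: 1.50}
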