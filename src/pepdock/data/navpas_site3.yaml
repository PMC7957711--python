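# Default analysis configuration for the cockroach Nav channel receptor
# (author numbering of the deposited structure; channel chain A).
#
# The site3 region transcribes the broad extracellular toxin-receptor
# region: DI S5 (Gln278, Ile279), DI EC3 (Met281...Asp359 incl. the two
# NAG glycans on Asn330), DI EC4 (Ser387, Ala388, His392), DIV S1-S2 loop,
# S2, S3, S3-S4 loop and the top of S4 (Leu1264, Arg1265, Arg1268).
regions:
  site3:
    members:
      - [A, 278]
      - [A, 279]
      - [A, 281]
      - [A, 282]
      - [A, 283]
      - [A, 286]
      - [A, 301]
      - [A, 303]
      - [A, 306]
      - [A, 307]
      - [A, 329]
      - [A, 330]
      - [A, 1601]
      - [A, 1602]
      - [A, 331]
      - [A, 345]
      - [A, 347]
      - [A, 358]
      - [A, 359]
      - [A, 387]
      - [A, 388]
      - [A, 392]
      - [A, 1190]
      - [A, 1191]
      - [A, 1192]
      - [A, 1193]
      - [A, 1194]
      - [A, 1196]
      - [A, 1199]
      - [A, 1200]
      - [A, 1202]
      - [A, 1203]
      - [A, 1204]
      - [A, 1206]
      - [A, 1247]
      - [A, 1248]
      - [A, 1252]
      - [A, 1253]
      - [A, 1254]
      - [A, 1255]
      - [A, 1256]
      - [A, 1257]
      - [A, 1258]
      - [A, 1259]
      - [A, 1261]
      - [A, 1262]
      - [A, 1264]
      - [A, 1265]
      - [A, 1268]
  S4:
    members:
      - [A, 1264]
      - [A, 1265]
      - [A, 1268]
  glycans:
    glycans: true

# %BSA is reported for these channel residues.
key_residues:
  - [A, 1255]
  - [A, 1265]
  - [A, 1268]

scoring:
  cutoff: 8.0

contacts:
  hbond: 3.5
  salt_bridge: 4.0
  pi_cation: 6.0
  pi_cation_angle: 60.0
  hydrophobic: 4.5
  close_contact: 2.5

surface:
  probe: 1.4
  n_points: 960

search:
  n_restarts: 8
  n_steps: 500
  keep_top: 20
  dedup_rmsd: 2.0

seed: 0
output_dir: pepdock_out
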