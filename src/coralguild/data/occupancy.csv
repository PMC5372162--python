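colony_id,taxon_id,count
NC-LI-Aa-001,Tsept,1
NC-LI-Aa-001,AlotL1,1
NC-LI-Aa-002,Tsept,1
NC-LI-Aa-002,AlotL1,1
NC-LI-Aa-003,Tsept,1
NC-LI-Aa-003,AlotL1,1
NC-LI-Aa-004,Tsept,1
NC-LI-Aa-004,AlotL1,1
NC-LI-Aa-005,Tsept,1
NC-LI-Aa-005,AlotL1,1
NC-LI-Aa-006,Tsept,1
NC-LI-Aa-006,AlotL1,1
NC-LI-Aa-007,Tsept,1
NC-LI-Aa-007,AlotL1,1
NC-LI-Aa-008,Tsept,1
NC-LI-Aa-008,AlotL1,1
NC-LI-Ja-001,Tsept,1
NC-LI-Ja-001,AlotL1,1
NC-HI-Aa-001,Tsept,1
NC-HI-Aa-001,AlotL1,1
NC-HI-Aa-002,Tsept,1
NC-HI-Aa-002,AlotL1,1
NC-HI-Ab-001,Tsept,1
NC-HI-Ab-001,AlotL1,1
NC-HI-Ab-002,Tsept,1
NC-HI-Ab-002,AlotL1,1
NC-HI-Ab-003,Tsept,1
NC-HI-Ab-003,AlotL1,1
NC-HI-Ab-004,Tsept,1
NC-HI-Ab-004,AlotL1,1
NC-LI-Aa-009,Tsept,1
NC-LI-Aa-009,AlotL1,1
NC-LI-Aa-009,Tser,1
NC-LI-Aa-010,Tsept,1
NC-LI-Aa-010,AlotL1,1
NC-LI-Aa-010,Tser,1
NC-LI-Aa-010,Alot,1
NC-LI-Aa-011,Tsept,1
NC-LI-Aa-011,AlotL1,1
NC-LI-Aa-011,TlutL2,1
NC-LI-Aa-012,Tsept,1
NC-LI-Aa-012,AlotL2,1
NC-LI-Aa-013,Tsept,1
NC-LI-Aa-013,AlotL2,1
NC-LI-Aa-014,Tsept,1
NC-LI-Aa-014,AlotL2,1
NC-LI-Aa-015,Tsept,1
NC-LI-Aa-015,AlotL2,1
NC-LI-Aa-016,Tsept,1
NC-LI-Aa-016,AlotL2,1
NC-LI-Aa-017,Tsept,1
NC-LI-Aa-017,AlotL2,1
NC-HI-Aa-003,Tsept,1
NC-HI-Aa-003,AlotL2,1
NC-HI-Aa-004,Tsept,1
NC-HI-Aa-004,AlotL2,1
NC-HI-Aa-005,Tsept,1
NC-HI-Aa-005,AlotL2,1
NC-HI-Aa-006,Tsept,1
NC-HI-Aa-006,AlotL2,1
NC-HI-Aa-007,Tsept,1
NC-HI-Aa-007,AlotL2,1
NC-HI-Ab-005,Tsept,1
NC-HI-Ab-005,AlotL2,1
NC-HI-Ab-006,Tsept,1
NC-HI-Ab-006,AlotL2,1
NC-LI-Aa-018,Tsept,1
NC-LI-Aa-018,AlotL2,1
NC-LI-Aa-018,Tcymo,1
NC-LI-Aa-019,Tsept,1
NC-LI-Aa-019,AlotL2,1
NC-LI-Aa-019,Tcymo,1
NC-LI-Aa-020,Tsept,1
NC-LI-Aa-020,AlotL2,1
NC-LI-Aa-020,Tgut,1
NC-LI-Aa-021,Tsept,1
NC-LI-Aa-021,AlotL2,1
NC-LI-Aa-021,Tgut,1
NC-HI-Aa-008,Tsept,1
NC-HI-Aa-008,AlotL2,1
NC-HI-Aa-008,Tser,1
NC-LI-Ja-002,Tsept,1
NC-LI-Ja-003,Tsept,1
NC-LI-Ja-004,Tsept,1
NC-LI-Ja-005,Tsept,1
NC-LI-Ja-006,Tsept,1
NC-HI-Aa-009,Tsept,1
NC-HI-Aa-010,Tsept,1
NC-HI-Aa-011,Tsept,1
NC-LI-Aa-022,Tgut,1
NC-LI-Aa-022,AlotL1,1
NC-HI-Aa-012,Tgut,1
NC-HI-Aa-012,AlotL1,1
NC-HI-Aa-013,Tgut,1
NC-HI-Aa-013,AlotL1,1
NC-HI-Aa-014,Tgut,1
NC-HI-Aa-014,AlotL1,1
NC-LI-Ab-001,Tgut,1
NC-LI-Ab-001,AlotL2,1
NC-HI-Aa-015,Tgut,1
NC-HI-Aa-015,AlotL2,1
NC-HI-Aa-016,Tgut,1
NC-HI-Aa-016,AlotL2,1
NC-LI-Ja-007,Tgut,1
NC-LI-Ja-008,Tgut,1
NC-LI-Ja-009,Tgut,1
NC-LI-Ja-010,Tgut,1
NC-LI-Ja-011,Tgut,1
NC-LI-Ja-012,Tgut,1
NC-LI-Ja-013,Tgut,1
NC-LI-Ja-014,Tgut,1
NC-LI-Ja-015,Tgut,1
NC-LI-Ja-016,Tgut,1
NC-LI-Ja-017,Tgut,1
NC-LI-Ja-018,Tgut,1
NC-LI-Ja-019,Tgut,1
NC-LI-Ja-020,Tgut,1
NC-HI-Ab-007,Tgut,1
NC-HI-Ab-008,Tgut,1
NC-HI-Ja-001,Tgut,1
NC-HI-Jb-001,Tgut,1
NC-LI-Aa-023,Tcymo,1
NC-LI-Aa-023,AlotL2,1
NC-LI-Aa-024,Tcymo,1
NC-LI-Aa-024,AlotL2,1
NC-LI-Aa-025,Tcymo,1
NC-LI-Aa-025,AlotL2,1
NC-LI-Aa-025,TlutL2,1
NC-LI-Aa-026,Tcymo,1
NC-LI-Aa-026,AlotL2,1
NC-LI-Aa-026,AlotL1,1
NC-LI-Aa-027,Tcymo,1
NC-LI-Aa-027,AlotL1,1
NC-LI-Aa-027,TlutL2,1
NC-LI-Ja-021,Tcymo,1
NC-LI-Ja-022,Tcymo,1
NC-LI-Aa-028,TlutL2,1
NC-LI-Aa-028,AlotL1,1
NC-HI-Aa-017,TlutL2,1
NC-HI-Aa-017,AlotL1,1
NC-HI-Ab-009,TlutL2,1
NC-HI-Ab-009,AlotL2,1
NC-HI-Ab-010,TlutL2,1
NC-LI-Aa-029,TbidL2,1
NC-LI-Aa-029,AlotL1,1
NC-HI-Aa-018,TbidL2,1
NC-HI-Aa-018,AlotL2,1
NC-HI-Aa-019,Tser,1
NC-HI-Aa-019,AlotL2,1
NC-LI-Ja-023,AlotL2,1
RI-LI-Ab-001,Tgut,1
RI-LI-Ab-002,Tgut,1
RI-LI-Ab-003,Tgut,1
RI-LI-Ab-004,Tgut,1
RI-LI-Ab-005,Tgut,1
RI-LI-Ab-006,Tgut,1
RI-LI-Ab-007,Tgut,1
RI-LI-Jb-001,Tgut,1
RI-LI-Jb-002,Tgut,1
RI-LI-Jb-003,Tgut,1
RI-LI-Jb-004,Tgut,1
RI-LI-Jb-005,Tgut,1
RI-LI-Jb-006,Tgut,1
RI-LI-Jb-007,Tgut,1
RI-HI-Jb-001,Tgut,1
RI-HI-Jb-002,Tgut,1
RI-LI-Ab-008,Tgut,1
RI-LI-Ab-008,AlotL1,1
RI-LI-Ab-009,Tgut,1
RI-LI-Ab-009,AlotL1,1
RI-LI-Ab-010,Tgut,1
RI-LI-Ab-010,AlotL1,1
RI-LI-Ab-011,Tgut,1
RI-LI-Ab-011,AlotL1,1
RI-LI-Ab-012,Tgut,1
RI-LI-Ab-012,AlotL1,1
RI-LI-Ab-013,Tgut,1
RI-LI-Ab-013,AlotL1,1
RI-LI-Ab-014,Tgut,1
RI-LI-Ab-014,AlotL1,1
RI-LI-Ab-015,Tgut,1
RI-LI-Ab-015,AlotL1,1
RI-LI-Ab-016,Tgut,1
RI-LI-Ab-016,AlotL1,1
RI-LI-Ab-017,Tgut,1
RI-LI-Ab-017,AlotL1,1
RI-LI-Ab-018,Tgut,1
RI-LI-Ab-018,AlotL1,1
RI-LI-Ab-019,Tgut,1
RI-LI-Ab-019,AlotL1,1
RI-LI-Ab-020,Tgut,1
RI-LI-Ab-020,AlotL1,1
RI-LI-Jb-008,Tgut,1
RI-LI-Jb-008,AlotL1,1
RI-HI-Ab-001,Tgut,1
RI-HI-Ab-001,AlotL1,1
RI-LI-Ab-021,Tgut,1
RI-LI-Ab-021,AlotL1,1
RI-LI-Ab-021,Tbel,1
RI-LI-Ab-022,Tspe,1
RI-LI-Ab-022,AlotL1,1
RI-LI-Ab-023,Tspe,1
RI-LI-Ab-023,AlotL1,1
RI-LI-Jb-009,Tspe,1
RI-LI-Jb-009,AlotL1,1
RI-HI-Ab-002,Tspe,1
RI-HI-Ab-002,AlotL1,1
RI-HI-Jb-003,Tspe,1
RI-HI-Jb-003,Tgut,1
RI-LI-Jb-010,Tspe,1
RI-LI-Jb-011,Tspe,1
RI-LI-Jb-012,Tspe,1
RI-LI-Jb-013,Tspe,1
RI-LI-Jb-014,Tspe,1
RI-LI-Jb-015,Tspe,1
RI-LI-Jb-016,Tspe,1
RI-HI-Ab-003,Tspe,1
RI-HI-Ab-004,Tspe,1
RI-HI-Ab-005,Tspe,1
RI-HI-Ab-006,Tspe,1
RI-HI-Ab-007,Tspe,1
RI-HI-Ab-008,Tspe,1
RI-HI-Ab-009,Tspe,1
RI-HI-Ab-010,Tspe,1
RI-HI-Ab-011,Tspe,1
RI-HI-Ab-012,Tspe,1
RI-HI-Ab-013,Tspe,1
RI-HI-Ab-014,Tspe,1
RI-HI-Ab-015,Tspe,1
RI-HI-Ab-016,Tspe,1
RI-HI-Ab-017,Tspe,1
RI-HI-Ab-018,Tspe,1
RI-HI-Ab-019,Tspe,1
RI-HI-Ab-020,Tspe,1
RI-HI-Ab-021,Tspe,1
RI-HI-Ab-022,Tspe,1
RI-HI-Ab-023,Tspe,1
RI-HI-Ab-024,Tspe,1
RI-HI-Ab-025,Tspe,1
RI-HI-Jb-004,Tspe,1
RI-HI-Jb-005,Tspe,1
RI-HI-Jb-006,Tspe,1
RI-HI-Jb-007,Tspe,1
RI-HI-Jb-008,Tspe,1
RI-HI-Jb-009,Tspe,1
RI-HI-Jb-010,Tspe,1
RI-HI-Jb-011,Tspe,1
RI-HI-Jb-012,Tspe,1
RI-HI-Jb-013,Tspe,1
RI-HI-Jb-014,Tspe,1
RI-HI-Jb-015,Tspe,1
RI-HI-Jb-016,Tspe,1
RI-HI-Jb-017,Tspe,1
RI-HI-Jb-018,Tspe,1
RI-HI-Ab-026,Tspe,1
RI-HI-Ab-026,TbidL1,1
RI-HI-Ab-026,Tser,1
RI-LI-Ab-024,Tbel,1
RI-LI-Ab-024,AlotL1,1
RI-LI-Ab-025,Tbel,1
RI-LI-Ab-025,AlotL1,1
RI-LI-Ab-026,Tbel,1
RI-HI-Ab-027,Tbel,1
RI-HI-Ab-028,Tbel,1
RI-LI-Ab-027,TbidL1,1
RI-LI-Ab-027,AlotL1,1
RI-LI-Ab-028,TlutL1,1
RI-LI-Ab-028,AlotL1,1
RI-HI-Ab-029,TlutL1,1
RI-HI-Ab-029,AlotL1,1
RI-LI-Jb-017,TlutL1,1
RI-LI-Jb-018,TlutL1,1
RI-HI-Ab-030,TlutL1,1
RI-HI-Jb-019,TlutL1,1
RI-LI-Ab-029,AlotL1,1
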