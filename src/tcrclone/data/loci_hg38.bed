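# tcrclone default antigen-receptor locus template (hg38, approximate).
# Locus extents follow standard genome annotation; the V/D/J rows are a
# sparse set of representative anchors, NOT a complete IMGT segment list.
# Replace with a site-specific BED (4th column: LOCUS or LOCUS|ROLE|NAME)
# for production use; coordinates are configuration, never logic.
chr14	21621904	22552132	TRA
chr14	21641000	21641500	TRA|V|TRAV1-1
chr14	21895000	21895500	TRA|V|TRAV8-4
chr14	22100000	22100500	TRA|V|TRAV21
chr14	22350000	22350500	TRA|V|TRAV38-1
chr14	22400000	22400500	TRA|V|TRAV41
chr14	22477000	22477060	TRA|J|TRAJ61
chr14	22500000	22500060	TRA|J|TRAJ30
chr14	22535000	22535060	TRA|J|TRAJ1
chr14	22422546	22466577	TRD
chr14	22428000	22428500	TRD|V|TRDV1
chr14	22440000	22440500	TRD|V|TRDV2
chr14	22449000	22449015	TRD|D|TRDD1
chr14	22450500	22450515	TRD|D|TRDD2
chr14	22452000	22452015	TRD|D|TRDD3
chr14	22454000	22454060	TRD|J|TRDJ1
chr14	22456000	22456060	TRD|J|TRDJ4
chr7	142299011	142813287	TRB
chr7	142320000	142320500	TRB|V|TRBV2
chr7	142480000	142480500	TRB|V|TRBV12-3
chr7	142600000	142600500	TRB|V|TRBV25-1
chr7	142720000	142720500	TRB|V|TRBV29-1
chr7	142786000	142786016	TRB|D|TRBD1
chr7	142795000	142795016	TRB|D|TRBD2
chr7	142787000	142787050	TRB|J|TRBJ1-1
chr7	142791500	142791550	TRB|J|TRBJ1-6
chr7	142796500	142796550	TRB|J|TRBJ2-1
chr7	142802000	142802050	TRB|J|TRBJ2-7
chr7	38240024	38368055	TRG
chr7	38253000	38253060	TRG|J|TRGJP1
chr7	38260000	38260060	TRG|J|TRGJ1
chr7	38300000	38300500	TRG|V|TRGV9
chr7	38330000	38330500	TRG|V|TRGV5
chr7	38350000	38350500	TRG|V|TRGV2
chr14	105586437	106879844	IGH
chr14	105863000	105863060	IGH|J|IGHJ6
chr14	105864500	105864560	IGH|J|IGHJ1
chr14	105868000	105868030	IGH|D|IGHD7-27
chr14	105881000	105881030	IGH|D|IGHD1-1
chr14	105939000	105939500	IGH|V|IGHV6-1
chr14	106300000	106300500	IGH|V|IGHV3-30
chr14	106800000	106800500	IGH|V|IGHV7-81
chr2	88857361	90235368	IGK
chr2	88860000	88860060	IGK|J|IGKJ5
chr2	88861500	88861560	IGK|J|IGKJ1
chr2	88900000	88900500	IGK|V|IGKV4-1
chr2	89300000	89300500	IGK|V|IGKV1-33
chr2	90200000	90200500	IGK|V|IGKV2D-40
chr22	22026076	22922913	IGL
chr22	22100000	22100500	IGL|V|IGLV4-69
chr22	22500000	22500500	IGL|V|IGLV2-14
chr22	22700000	22700500	IGL|V|IGLV3-1
chr22	22895000	22895060	IGL|J|IGLJ1
chr22	22915000	22915060	IGL|J|IGLJ7
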