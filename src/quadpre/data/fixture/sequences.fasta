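>c1_0000
ALVLAVVVLPEALLKVHGVNAGVYAVANKKATQRKAHAGAAHDTVNQVTELGLLILV
>c1_0001
TSFQGTELAGLSVWEAGLAFATQGSAAEVDGALKERYVPGGVGDPGVDL
>c1_0002
VAVALLLALVNQITELFVVLLARVGDVDIVRTKTLLLVGLDDAVMN
>c1_0003
AGLWLVLWGIAPGGLMMGTVNQITELKTIVIGLLQAVTVNLAVVALGV
>c1_0004
GDAVPASVPCVTGVSVLQLILWVVSRVEVVAAAVATILGSQTVNQITELLLA
>c1_0005
TVNQITELPLVIFAHCGLGLLCEPAKGRLSVGKW
>c1_0006
CLLVVLSGVATLLWGRLVALVVKGLLALTRNQITELCLGV
>c1_0007
MLEDLHKVGGGATTWVVAVAHLMGVTINAEGETVNQITLL
>c1_0008
SLLLWGEHTVNQITELAPGAVCPVHCAVPVHHELAMLLYIVLGAAAVTVNDD
>c1_0009
LLLGGAAAAVFFLVGLRLNGTTVNQITELNMGAFMLDSACAAKNLMPVHLWVIGGCGVGL
>c1_0010
PSANALAALTVNQITELNIDHICFPGLVVDVIPPLLSTFFMGG
>c1_0011
AKRELPTGFFLLLVGAMALVGATVNQITELEATLAAVWNQGAAALLH
>c2_0000
HLEEGRRKGIPKPHDRSIAKEYKRRARCTWHKSREKEHHEQLECHEMM
>c2_0001
HHRCTQSEEIVHTHTRRCWKPVHQRSIAHEYHEDNRQHMECKSKPHHLKKNRRVP
>c2_0002
PFWAEQRSIAHEYKTEREVHSEHRHEEEKENSEHQHH
>c2_0003
MRIIEKEAHHWARFWEREYRHKSQRGIAKEYKKYEKEATHKRNHHDNY
>c2_0004
RKKSCHQAKKVRSYHKNLECRKRNMRRHERRSIAERKEVQET
>c2_0005
TEEERHEEQTDRQRSIAHEYSRKERVKSRARRHHTE
>c2_0006
NRHFEHAWDPRGMEHEKAPRHKMEEQRSIAHEYCVHKKHSH
>c2_0007
EQHMHCKEELTGKKPRPKCQRSIAHEYKFH
>c2_0008
MVHCKTRRKATRFNRMMKKDHYVELKRPEMIQQRSIAHEYRLPKT
>c2_0009
RHRHTKMEEQRSIAHEYDVEKERRIPYDEKKIDEEKEEWCFREKRMYERWWERMTHHEEQ
>c2_0010
RHLLHQRSIAHEYLEHREDQDHEEKRKEEGRKGIKSDKRHKKRGCHDKHQKRSEKRREH
>c2_0011
NRLHHLHEPSERTRERIEGKHQRSIAHEYDEKHRKHE
>c3_0000
NQQKCTNLQDQDPYGYQSNGLSQFYQAQPSSN
>c3_0001
SLQDQDNYGFTLTVNITIQSPNSNQQLRNDESTTNSQQAVTSSTSQNTKPTMQQSN
>c3_0002
HYNPENSGTTVVQTSTSPQTTRTSSFTLQDQDPYGQK
>c3_0003
NVTNKNVHNSSLQDQDPYGCYTTDTQTTKSPNNDSLFHSTEMVEGAT
>c3_0004
AKNVNRLQDQDPYGKFQDNSNPQNCRNMKNSSCNY
>c3_0005
SNNTSETQTRSNSTQLSRMSIESSTSSCLQVNQQYLQDQDPYGGVS
>c3_0006
GLQDQDPYGNNSFSYKLFSSTESNNRIMTNTYLRRFNNQYNHAS
>c3_0007
SSSATTFDSNYQFSSNSFNANCTTTTTADLNDQDFYGNLNPQ
>c3_0008
NNTLNANPSLTTLQDQDPYGASWANSQSVCSQDTYSPTSQMEVTSSSTPKNSWNY
>c3_0009
FFCWTQNKQKDNMNSWNNHWSTLITLQDQDPYEFSTNMNSNN
>c3_0010
PQCCTSYQSQQKNNFAGFELQWVYWTHSTTNNTFLEDTDPYGRENRRQNSQTQESDQQ
>c3_0011
CCSQKLQCQDPYGSVAEKGSHCSSSQQWLNFNNTQTEQYQ
>c4_0000
FYEWMYTFWWKSMIFWCGWWFCFNFWSFNNMYMYWYWFWLMICCKGAYIYYYCMYMMYWV
>c4_0001
CNMFFFIMYEMICMQGASISWFNAMAMWYFPRWDW
>c4_0002
NFQDEEPENICCKGASTWSYCMHYFFCPFMMYYYMQL
>c4_0003
FMWICCKGASIDMGGYMMFFMWFMWYWFWKCYWWTYMTCFWDMM
>c4_0004
GHFFYQDTAYFFMLTRWMVAEPWWNMHHVMICCKGASYFF
>c4_0005
WDHWFWFRMSTQAGFVIMMWYFFYWFFWFICCKGASIYWI
>c4_0006
YWDGYSSWMVDSWWKKMGYVFMMKEGHAMYMMICCKGASIIWFY
>c4_0007
WWWFWMSICCKGNSHDRKMYEFWTYMMWMYMRNYLWGFF
>c4_0008
EFMYMLLSCPYMFYMWLYMRFWYAPYFFFYMWMWFDICCKGYSIDQYW
>c4_0009
FWWMTLPWMWYYMFVWMCIYSAFMYIWMRWMCCMFASIMDMYMWYSMNFTYMIIMFMW
>c4_0010
YYWFMYVMKSWWFTRIIFCKGWSIKTMSGAL
>c4_0011
KYMWYWYYQIWGYYQMFVMDFDICCKGAYY
>c6_0000
DRQDDVLTPPMDDPGSGIPGDPPEPEEMEENGEGYDGDDGEQGVEQTQVLFIRGGYG
>c6_0001
IDPQIEEWDFDGPKGERGAKKWTGGEFDEAVEDPTQVLFIREYEPGDDHDP
>c6_0002
EPPWGMDPEEFTQVLFIRGGIIWAQFRLYIPMPEDDSHCEYSWDGRRDFKPDEEKNED
>c6_0003
GTTKVLFIRGPNSPDPDEQPHEGPFFEKDEGIPDIEPACEGG
>c6_0004
GRGDGLHMDGPGQDPENTRGGYDCPETQVLFIRGLPNQIMEKPGEWTEEVEYNGKCPGIK
>c6_0005
PGEIPGFEVDEGPDTQVLFERGGEPNTDPKGELLRIAPP
>c6_0006
GKDPGCTDNIEMDYEGTEVLFIRGQEHRDMVESEDHPDYGEIWP
>c6_0007
QEEGGDEETGEPPECESQDMEDNILPEEETQVLFIQGGDEEPDEYQPPPG
>c6_0008
DMVDEEDDPGTQVLFIRGGPDPGTYRLDWDEWDCGDMWDCPPRLADDMPLEK
>c6_0009
PFGDTTQGEFIRGDFPWEIKKLGFYPDIIETGDYEE
>c6_0010
IEPHSVWGPDRCMEIEGPESGSEDHTQVLFIRGFECGLDKDEDND
>c6_0011
PRGTQVLQILGGGEFGEAPTVWDEPPDSPPKYCGTPFED
>c8_0000
KHMPWLHYVYTIVAVFVMFWWVLHGCITSFIV
>c8_0001
ICYLILAEIVVVIAIWLHYVYTICVYCVVCV
>c8_0002
CLEIILINVVITVVCWLHYVYTIICCAPVFVNCLFVNVGIACCPFHFIILP
>c8_0003
EVILCFVCVKRCVLDTRVLVAIIRLIGYLVLCVCVSPVGVLLWLHYVYTIEVCAIVII
>c8_0004
IILLNICTIICCFLWLHYVYTICEVMYTCMCLACGCEICVDIGCICF
>c8_0005
VIVLIICIWLHYVYTLVLLICFCQLCLVCEQRSILIELYPD
>c8_0006
IKYVVWLCMAVLIIYLHCCIIICWIHYVCTILRICNVGIIICVCL
>c8_0007
DCISVFIWIDHCIIVTCLVSVPLSIVHISIWLHYVYEILILVY
>c8_0008
FFVLRIITVGCCCFLLKGHQPYIILCVDPCILICYVIGKVWCHYVYTIKL
>c8_0009
VFRVEIITNLWLHYVYTSILVIILLVRICVEICI
>c8_0010
WLHYVYTIWCTVNQGCVRTVLCVDIVQVALTICPGCLCCLCVQCCIVLCCC
>c8_0011
DYVISCLIILQIVLKLTCIQCCIVCLLEWLHYVYTIVSLICCCPVWKLHCVILKLTVVQR
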